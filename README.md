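# pterrace

Partial phylogenetic terraces under NNI, SPR and TBR rearrangements.

## The problem

Phylogenomic tree searches on partitioned supermatrices score a candidate
species tree `T` as the sum of scores of its *induced partition trees*
`T|Y_i` — the tree pruned down to the taxa `Y_i` that actually have data for
partition `i`, with degree-2 nodes suppressed. Sparse supermatrices (30–70%
missing data is common) make many partitions blind to many parts of the
tree: a topological rearrangement of `T` often leaves some, or all, `T|Y_i`
unchanged. Trees whose induced partition trees all coincide form a
*terrace* (identical score under edge-unlinked partition models); trees
sharing only a subset of partition trees form a *partial terrace*, and the
shared partitions need no re-scoring when the search moves between them.

`pterrace` implements exact, bit-set-level predicates that decide — without
building a single restricted tree — whether a rearrangement changes each
partition tree:

* **NNI** around an interior edge with incident subtree taxon sets
  `A, B, C, D`: the partition tree changes **iff** `Y` has at least one
  representative in each of `A, B, C, D`. Then `RF(T|Y, T_NNI|Y) = 2`,
  otherwise 0.
* **SPR** pruning subtree `A` across path subtrees `B_1..B_n`
  (`RF(T, T_SPR) = 2(n−2)`): the partition tree changes iff `Y` meets `A`
  and at least three of the `B_i`. The move induced on `T|Y` prunes
  `A∩Y` and regrafts at `B_k∩Y` with `k = max{i : B_i∩Y ≠ ∅}` — a long SPR
  on the species tree is typically a much shorter SPR (often an NNI) on the
  partition tree.
* **TBR** bisecting an edge with side path subtrees `B_1..B_n` and
  `C_1..C_m` (`RF(T, T_TBR) = 2(n+m−4)`): the partition tree changes iff
  `Y` is represented in at least one subtree on one side and at least three
  on the other; the symmetric 2+2 configuration never changes it. The
  induced TBR cuts `(∪B_i)∩Y | (∪C_j)∩Y` and reconnects at `B_k∩Y` and
  `C_h∩Y` (maxima of the represented indices).

On top of the predicates sit whole-neighborhood sweeps: every NNI neighbor
of a tree is binned by its fraction of shared partition trees ("No PT",
PT1–PT10, "Full terrace"), and the mean shared fraction across the
neighborhood is the estimated fraction of partition-tree evaluations a
search could skip.

The package also provides the supporting machinery as a tested library:
unrooted binary trees with canonical split bit-vectors, Robinson–Foulds
distance via split-set symmetric difference, induced-subtree restriction,
move enumeration/application, Yule–Harding random trees, random coverage
matrices with a target missing fraction, and readers for FASTA /
relaxed-PHYLIP supermatrices with RAxML-style partition files.

## Worked example

Simulate a sparse supermatrix regime and sweep an NNI neighborhood:

```bash
pterrace simulate --taxa 20 --partitions 8 --missing 0.5 --seed 42 --out demo
pterrace neighborhood --tree demo.nwk --coverage demo.coverage.tsv --out demo_nb
```

```
coverage: 20 taxa x 8 partitions, realized missing 52.50% (target 50.00%)
neighborhood size: 34
  PT2: 2 (5.88%)
  PT4: 4 (11.76%)
  PT5: 2 (5.88%)
  PT7: 6 (17.65%)
  PT8: 10 (29.41%)
  PT9: 4 (11.76%)
  Full terrace: 6 (17.65%)
savings estimate: 69.12%
```

All 34 = 2(20−3) NNI neighbors of the random 20-taxon tree were classified.
Six neighbors lie on the same full terrace as the input tree (identical
score, no recomputation at all); most others share 70–90% of their
partition trees. On average 69% of the per-partition score evaluations in
this neighborhood could be skipped. The per-neighbor detail lands in
`demo_nb.neighbors.tsv`:

```
edge	exchange	shared	total	fraction	bin
t01|t16	e1<->e3	8	8	1.0	Full terrace
t01|t16	e1<->e4	8	8	1.0	Full terrace
```

The same works from an alignment: pass `--alignment supermatrix.fasta
--partitions parts.txt` instead of `--coverage`, and presence/absence is
extracted per partition block (a taxon counts as present with ≥ 1
non-missing character; `?`, `-`, `N`, `X`, `.` are missing). Single moves
can be queried with `pterrace check-move --nni <edge>` (or `--spr`,
`--tbr`), which prints per-partition changed/unchanged verdicts, the reason,
and the induced move splits; `pterrace compare` reports the shared fraction
for two explicit trees.

As a library:

```python
import pterrace as pt

tree = pt.parse_newick("((a,(b,c)),(d,(e,f)));")
move = pt.enumerate_nni_moves(tree)[0]
y = tree.taxa.mask_of(["a", "b", "d", "e"])
pt.nni_changes_partition(move, y).changed   # quartet-representation test
```

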
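# Methods

## Model and scope

`pterrace` works with unrooted, fully bifurcating, leaf-labeled trees on a
taxon set `X`. Every edge `e` induces a split `A|B` of `X`; `Σ(T)` is the
collection of splits over all `2n−3` edges (`n` of them trivial). Two trees
are topologically identical iff their split collections coincide
(splits-equivalence theorem), and the Robinson–Foulds distance is
`|Σ(T₁) Δ Σ(T₂)|`. The induced partition tree for a partition with taxon
set `Y ⊆ X` is `T|Y`, whose split collection is
`{A∩Y | B∩Y : A|B ∈ Σ(T), both intersections non-empty}` — duplicates from
distinct edges of `T` are collapsed (set semantics), which matches the
structural construction (prune leaves outside `Y`, suppress degree-2
nodes).

The package decides, for each of the three standard rearrangements of a
species tree, whether each induced partition tree changes, maps a changing
SPR/TBR to the move it induces on the partition tree, and aggregates these
decisions over rearrangement neighborhoods into partial-terrace statistics.
Likelihood/parsimony scoring, branch-length optimization and tree search
itself are out of scope; `edge_affects_partition` exposes only the
linked-model observation that an edge whose split has an empty intersection
with `Y` on one side has no counterpart edge on `T|Y`.

## Representation choices

Splits are fixed-width integer bit-vectors over a global `TaxonIndex`; the
canonical stored side is the one *not* containing the lowest-ranked leaf of
the tree's leaf set, so `A|B` and `B|A` hash and compare equal in O(1).
Restricted trees keep the parent analysis' `TaxonIndex` (their leaf set is
a mask), so splits of `T|Y` and `T′|Y` are directly comparable without
relabeling. All topology comparisons go through split sets; node identity
is never compared. Edge lengths are parsed and carried through
serialization but excluded from every equivalence test. Trees with fewer
than four leaves carry no internal split and are defined as equivalent
whenever their leaf sets match; restriction may legally return one- or
two-leaf trees. Multifurcating input is rejected unless explicitly allowed,
and every operation that needs binarity validates it.

Newick output is deterministic: the tree is written rooted at the internal
node adjacent to the lowest-ranked leaf, children ordered by the smallest
taxon rank in their subtree. Parsing accepts rooted-at-a-bifurcation input
and suppresses the degree-2 root.

## Moves and their contexts

A move is a value object bound to one tree snapshot, addressed by the
canonical splits of the edges it touches (not by node identity), so a stale
move applied to a structurally different tree fails fast. Each move
eagerly resolves the taxon sets that drive both the split algebra and the
terrace predicates:

* **NNI**: interior edge plus the four incident subtree sets `A, B, C, D`.
  Convention: the endpoint on the side containing the tree's lowest-ranked
  leaf hosts `(A, B)`; within an endpoint the subtree with the smaller
  minimum rank comes first; the two moves per edge are named by whether
  `A` swaps with `C` or with `D`. RF to the neighbor is always 2.
* **SPR**: the pruned side of the prune edge is the component not
  containing the regraft edge, removing any need for a separate
  orientation flag. The path decomposition `B_1..B_n` is collected by
  walking from the attachment node to the regraft edge; `B_n` is the
  component beyond it. `n ≥ 3` is enforced (placements with `n < 3` are
  the identity and rejected); `n = 3` is flagged NNI-equivalent.
  RF = 2(n−2).
* **TBR**: the B side is the component containing the first reconnect
  edge; both sides get the same path decomposition, `n, m ≥ 2`, and
  `n = m = 2` is rejected as the identity. The bisection split itself is
  preserved by the move (it becomes the new connecting edge).
  RF = 2(n+m−4).

SPR/TBR enumeration is provided as plumbing with a radius cap (default 5)
because practical searches use short moves; predicates and application
accept arbitrary moves.

## The change predicates

The predicates operate purely on bit-masks — emptiness tests of
intersections with `Y` — never on restricted trees:

| move | changes `T|Y` iff |
|---|---|
| NNI | `A∩Y, B∩Y, C∩Y, D∩Y` all non-empty |
| SPR | `A∩Y ≠ ∅` and ≥ 3 of `B_1..B_n` represented |
| TBR | ≥ 1 represented on one side and ≥ 3 on the other |

All three are implemented as exact characterizations (iff). For SPR and
TBR the forward direction follows from the changed-split families; the
converse holds because a change requires the restricted tree to retain a
quartet around the rearranged region, which pins down the minimum
representation counts. The randomized oracle suite (restrict both trees,
compare split sets; 500+ triples per move kind, trees of 6–25 taxa, `|Y|`
from 1 to n) enforces exactness rather than leaving it to the argument.
A `Y` with at most three taxa can never change (no internal split exists);
the predicates short-circuit this case with a distinct reason code so
coverage audits can tell it apart from an empty intersection. Reports carry
machine-readable reason codes (`changed`, `too_few_taxa`,
`empty_intersection`, `no_quartet`) for savings accounting.

When a change fires, the induced move is reported in split form:
for SPR, prune `A∩Y | (∪B_i)∩Y` and regraft at `B_k∩Y` with
`k = max{i : B_i∩Y ≠ ∅}`; for TBR, cut `(∪B_i)∩Y | (∪C_j)∩Y` and reconnect
at `B_k∩Y` and `C_h∩Y`. When only one subtree of a TBR side is
represented, that reconnect split coincides with the cut split; the induced
move then degenerates to an SPR reattaching the whole side component, and
`apply_induced_move` handles this case explicitly. Soundness — applying
the induced move to `T|Y` reproduces `T_move|Y` at RF 0 — is part of the
oracle suite.

## Terrace comparison and binning

`compare_trees` is the reference path (restrict and compare per
partition); `compare_trees_fast` answers identically from the predicates
alone and is the path every sweep uses. Shared fractions are binned by
exact integer arithmetic on `(shared, total)` — `PTq` holds fractions in
`((q−1)/10, q/10]`, decided by comparing `10·shared` with `q·total` — so
the decile boundaries are bit-exact. The boundary asymmetry is
deliberate: `PT1..PT9` are right-closed, `PT10` is open at 100%, and the
extremes 0% / 100% are their own bins ("No PT" / "Full terrace").

Neighborhood sweeps stream one neighbor at a time. The savings estimate is
100 × the mean shared fraction over the neighborhood, with all partitions
weighted equally; aggregation over several trees reports both the per-tree
and the pooled per-neighbor average, which differ when neighborhood sizes
differ. Taxa covered by no partition are tolerated with a warning (they
belong to no `Y_i`); partitions covering no taxon are an error.

## Synthetic data

`yule_harding_tree` grows a random-branching tree: start from two leaves,
attach each next taxon to a uniformly chosen pendant edge, leave the tree
unrooted, and assign labels by a random permutation. The construction is
pinned by the property that the three unrooted 4-taxon topologies are
equiprobable (chi-square at α = 0.01 over 3000 draws) rather than by any
particular implementation detail.

`random_coverage` draws i.i.d. presence with probability
`1 − missing_fraction` and then repairs the grid to meet two constraints:
each partition keeps at least `min_partition_taxa` (default 4) present
taxa, and each taxon at least one partition. Repair flips only
absent→present cells and flips the provable minimum: column deficits are
hard lower bounds, and a maximum bipartite matching assigns uncovered rows
to deficit slots so no flip is wasted (verified against exhaustive search
on small grids). For grids of ≥ 100 cells the realized missing fraction
stays within about ±2 percentage points of the target; the default
regimes used in tests (30–72% missing, up to 128 taxa × 32 partitions)
mirror published sparse supermatrices.

`synthetic_supermatrix` writes a concatenated alignment (uniform random
A/C/G/T blocks for present cells, all-`?` otherwise) plus a RAxML-style
partition file, with the round-trip guarantee that coverage extraction
recovers the input grid exactly. The generator makes no attempt to
simulate sequence evolution, phylogenetic signal, or biased missingness
patterns (e.g. clade-correlated gene absence); passing tests therefore
demonstrate correctness of the combinatorics on realistic sparsity
*patterns*, not anything about inference quality on real data.

## Numerical and scale choices

Everything is exact integer/bit-set arithmetic; the only floating-point
quantities are reported fractions and percentages. Randomized suites use
fixed seeds (hypothesis derandomized) and deliberately moderate sizes —
trees of 6–40 taxa for oracle comparisons, one 128-taxon × 32-partition
end-to-end run — chosen so the full suite completes in seconds while still
exercising every degenerate case we know of: `|Y| ≤ 3`, single-leaf pruned
subtrees, NNI-equivalent SPRs (`n = 3`), SPR-equivalent TBRs (`m = 2`),
degenerate induced TBRs, and restrictions to one- and two-leaf trees.

## Known limitations

* Predicates assume fully binary species trees; polytomies are rejected
  rather than handled by a polytomy-aware RF variant.
* `check-move --nni` reports the first (A↔C) exchange of the named edge;
  the second exchange has the same change predicate, so the per-partition
  verdicts are identical either way.
* Terrace *enumeration* (listing all trees on a terrace) and supertree
  construction are intentionally absent.
* Savings estimates weight partitions equally; a weight vector (e.g.
  alignment lengths) changes the numbers but not the machinery, and can be
  applied downstream from the per-partition booleans in each report.
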
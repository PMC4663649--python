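"""Synthetic study material: random trees, coverage matrices, supermatrices.

The generator mirrors the study conditions of sparse phylogenomic
supermatrices: Yule--Harding random topologies as the null tree
distribution, and taxa x partitions coverage grids with a target
missing-data percentage in the regime reported for published supermatrices
(roughly 30--72% missing).  Sequence content is uniform random nucleotides;
only presence/absence matters to any downstream computation here, so the
generator stays model-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .terrace import CoverageMatrix
from .treecore import PhyloTree, TaxonIndex, TreeError

__all__ = [
    "SimulationConfig",
    "yule_harding_tree",
    "random_coverage",
    "synthetic_supermatrix",
    "random_taxon_subset",
]

_MISSING_CHAR = "?"
_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Dimensions and sparsity of a synthetic coverage grid.

    ``missing_fraction`` is a target; for grids of at least 100 cells the
    realized fraction after constraint repair stays within about two
    percentage points of it.  ``min_partition_taxa`` guarantees every
    partition tree has enough leaves to carry topology (4 by default).
    """

    n_taxa: int
    n_partitions: int
    missing_fraction: float
    seed: int
    min_partition_taxa: int = 4

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.n_partitions < 1:
            raise ValueError("need at least 1 partition")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.min_partition_taxa > self.n_taxa:
            raise ValueError(
                "min_partition_taxa exceeds the number of taxa: infeasible"
            )


def _default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def yule_harding_tree(
    n_taxa: int,
    seed: int | np.random.Generator,
    taxa: TaxonIndex | None = None,
) -> PhyloTree:
    """Random-branching (Yule--Harding) tree on ``n_taxa`` leaves.

    Growth starts from a two-leaf tree; each subsequent taxon is attached
    to a uniformly chosen pendant edge (equivalently, a uniformly chosen
    current leaf is split into a cherry).  The result is unrooted by
    construction and the taxon labels are assigned by a random permutation,
    so the three unrooted quartet topologies are equiprobable at n = 4.
    Deterministic for a fixed seed.
    """
    if n_taxa < 3:
        raise ValueError("Yule-Harding growth needs at least 3 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if taxa is None:
        taxa = TaxonIndex(_default_labels(n_taxa))
    elif len(taxa) != n_taxa:
        raise ValueError("TaxonIndex size does not match n_taxa")

    ranks = rng.permutation(n_taxa)
    tree = PhyloTree(taxa)
    first = tree._new_node(int(ranks[0]))
    second = tree._new_node(int(ranks[1]))
    tree._add_edge(first, second)
    pendant_leaves = [first, second]
    for i in range(2, n_taxa):
        target = pendant_leaves[int(rng.integers(len(pendant_leaves)))]
        (anchor,) = tree._adj[target]
        new_internal = tree._new_node()
        new_leaf = tree._new_node(int(ranks[i]))
        tree._remove_edge(target, anchor)
        tree._add_edge(anchor, new_internal)
        tree._add_edge(new_internal, target)
        tree._add_edge(new_internal, new_leaf)
        pendant_leaves.append(new_leaf)
    tree.validate()
    return tree


def random_taxon_subset(
    taxa: TaxonIndex, size: int, rng: np.random.Generator
) -> int:
    """Bit-mask of a uniformly chosen taxon subset of a given size."""
    if not 1 <= size <= len(taxa):
        raise ValueError("subset size out of range")
    picks = rng.choice(len(taxa), size=size, replace=False)
    return int(sum(1 << int(i) for i in picks))


def random_coverage(
    config: SimulationConfig, taxa: TaxonIndex | None = None
) -> CoverageMatrix:
    """Random presence/absence grid with the target missing fraction.

    Cells are i.i.d. present with probability ``1 - missing_fraction``; the
    grid is then repaired to satisfy the per-partition minimum and the
    one-partition-per-taxon floor by flipping the fewest absent cells
    possible.  Flips that fix a deficient partition are matched to
    uncovered taxa first (a maximum bipartite matching), so no flip is
    wasted.  Seed-deterministic.
    """
    rng = np.random.default_rng(config.seed)
    if taxa is None:
        taxa = TaxonIndex(_default_labels(config.n_taxa))
    elif len(taxa) != config.n_taxa:
        raise ValueError("TaxonIndex size does not match config.n_taxa")

    present = rng.random((config.n_taxa, config.n_partitions)) >= config.missing_fraction
    present = _repair_coverage(present, config.min_partition_taxa, rng)
    return CoverageMatrix(taxa, _default_partition_names(config.n_partitions), present)


def _default_partition_names(p: int) -> list[str]:
    width = len(str(p))
    return [f"p{str(j + 1).zfill(width)}" for j in range(p)]


def _repair_coverage(
    present: np.ndarray, min_partition_taxa: int, rng: np.random.Generator
) -> np.ndarray:
    """Flip the minimum number of absent cells so that every partition has
    at least ``min_partition_taxa`` taxa and every taxon at least one
    partition.

    Column deficits are hard lower bounds on the flip count; a maximum
    bipartite matching assigns uncovered taxon rows to deficit flip slots
    so that each such flip serves both constraints whenever possible.
    """
    present = present.copy()
    n_taxa, n_parts = present.shape
    deficits = {
        j: max(0, min_partition_taxa - int(present[:, j].sum()))
        for j in range(n_parts)
    }
    empty_rows = {i for i in range(n_taxa) if not present[i].any()}

    # Matching: uncovered row i can fill a deficit slot of column j iff the
    # cell (i, j) is absent (always true for an all-absent row).
    graph = nx.Graph()
    slot_ids = []
    for j, d in deficits.items():
        for s in range(d):
            slot = ("slot", j, s)
            slot_ids.append(slot)
            for i in empty_rows:
                graph.add_edge(("row", i), slot)
    matching = nx.bipartite.maximum_matching(
        graph, top_nodes=[("row", i) for i in empty_rows]
    ) if graph.number_of_edges() else {}

    matched_rows_by_col: dict[int, list[int]] = {j: [] for j in deficits}
    for key, val in matching.items():
        if key[0] == "row":
            _, j, _s = val
            matched_rows_by_col[j].append(key[1])

    for j, d in deficits.items():
        if d == 0:
            continue
        chosen = list(matched_rows_by_col[j])[:d]
        if len(chosen) < d:
            pool = np.flatnonzero(~present[:, j])
            pool = [i for i in pool if i not in chosen]
            extra = rng.choice(len(pool), size=d - len(chosen), replace=False)
            chosen.extend(pool[int(e)] for e in extra)
        for i in chosen:
            present[i, j] = True
            empty_rows.discard(i)

    for i in sorted(empty_rows):
        j = int(rng.integers(n_parts))
        present[i, j] = True
    return present


def synthetic_supermatrix(
    tree: PhyloTree,
    cov: CoverageMatrix,
    part_len: int,
    seed: int | np.random.Generator = 0,
    fmt: str = "fasta",
) -> tuple[str, str]:
    """Concatenated alignment + RAxML-style partition file for a coverage.

    Each taxon's block for partition ``j`` is random A/C/G/T of length
    ``part_len`` when present, otherwise all ``'?'``.  Round-trip
    guarantee: coverage extracted from the emitted pair equals ``cov``
    cell-for-cell.
    """
    if part_len < 1:
        raise ValueError("part_len must be at least 1")
    if tree.leaf_mask != cov.taxa.full_mask or tree.taxa != cov.taxa:
        raise TreeError("tree taxa must equal coverage taxa")
    if fmt not in ("fasta", "phylip"):
        raise ValueError(f"unknown alignment format: {fmt}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    names = list(cov.taxa.names)
    rows = []
    for i, name in enumerate(names):
        blocks = []
        for j in range(cov.n_partitions):
            if cov.present[i, j]:
                blocks.append(
                    "".join(rng.choice(_NUCLEOTIDES, size=part_len))
                )
            else:
                blocks.append(_MISSING_CHAR * part_len)
        rows.append("".join(blocks))

    if fmt == "fasta":
        aln = "".join(f">{name}\n{seq}\n" for name, seq in zip(names, rows))
    else:
        total = cov.n_partitions * part_len
        body = "\n".join(f"{name}  {seq}" for name, seq in zip(names, rows))
        aln = f"{len(names)} {total}\n{body}\n"

    lines = []
    for j, pname in enumerate(cov.partitions):
        start = j * part_len + 1
        end = (j + 1) * part_len
        lines.append(f"DNA, {pname} = {start}-{end}")
    return aln, "\n".join(lines) + "\n"
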
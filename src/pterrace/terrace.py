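"""Partial and full terraces under a taxon x partition coverage matrix.

Two species trees lie on one *full terrace* when every induced partition
tree coincides; they lie on a *partial terrace* when a proper, non-empty
subset coincides.  Shared partition trees keep their likelihood/parsimony
contribution under edge-unlinked partition models, so the shared fraction
is a direct estimate of the computation a tree search can skip when moving
from one tree to the other.

This module bins a pair's shared fraction into the standard 12 bins
("no PT", PT1..PT10, "full terrace"), sweeps whole NNI neighborhoods with
the fast predicates of :mod:`pterrace.terracecond`, and aggregates the
per-neighbor results into a summary with a savings estimate (the mean
shared fraction across the neighborhood, in percent).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .rearrange import Move, enumerate_nni_moves
from .terracecond import Reason, changes_partition
from .treecore import (
    PhyloTree,
    TaxonIndex,
    TreeError,
    restrict,
    trees_equivalent,
)

__all__ = [
    "CoverageMatrix",
    "BinLabel",
    "classify_bin",
    "PairComparison",
    "compare_trees",
    "compare_trees_fast",
    "NeighborhoodSummary",
    "nni_neighborhood_summary",
    "iter_neighborhood",
    "savings_estimate",
    "aggregate_summaries",
]


# ---------------------------------------------------------------------------
# Coverage matrix
# ---------------------------------------------------------------------------


class CoverageMatrix:
    """Binary taxa x partitions presence/absence grid.

    Row order follows the :class:`TaxonIndex`; ``y_mask(i)`` is the taxon
    set of partition ``i`` as a bit-vector, ready for the terrace
    predicates.  Partitions with no present taxon are rejected; taxa with
    no partition are tolerated with a warning (they simply belong to no
    ``Y_i``), mirroring rows that occur in real sparse supermatrices.
    """

    def __init__(
        self,
        taxa: TaxonIndex,
        partitions: Sequence[str],
        present: np.ndarray,
    ):
        present = np.asarray(present, dtype=bool)
        if present.shape != (len(taxa), len(partitions)):
            raise ValueError(
                f"coverage grid shape {present.shape} does not match "
                f"{len(taxa)} taxa x {len(partitions)} partitions"
            )
        if len(set(partitions)) != len(partitions):
            raise ValueError("duplicate partition identifiers")
        empty_parts = [p for j, p in enumerate(partitions) if not present[:, j].any()]
        if empty_parts:
            raise ValueError(f"partitions with no present taxon: {empty_parts}")
        uncovered = [taxa.label(i) for i in range(len(taxa)) if not present[i].any()]
        if uncovered:
            warnings.warn(
                f"taxa covered by no partition: {uncovered}; they belong to "
                "no partition taxon set",
                stacklevel=2,
            )
        self.taxa = taxa
        self.partitions = tuple(partitions)
        self.present = present
        self._y_masks = tuple(
            int(sum(1 << i for i in range(len(taxa)) if present[i, j]))
            for j in range(len(partitions))
        )

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def y_mask(self, j: int) -> int:
        return self._y_masks[j]

    def y_labels(self, j: int) -> tuple[str, ...]:
        return self.taxa.labels_of(self._y_masks[j])

    @property
    def missing_fraction(self) -> float:
        return 1.0 - float(self.present.mean())

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            self.present.astype(int),
            index=list(self.taxa.names),
            columns=list(self.partitions),
        )
        df.index.name = "taxon"
        df.to_csv(path_or_buf, sep="\t")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "CoverageMatrix":
        df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
        taxa = TaxonIndex(str(t) for t in df.index)
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("coverage TSV cells must be 0 or 1")
        return cls(taxa, [str(c) for c in df.columns], values.astype(bool))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"CoverageMatrix({len(self.taxa)} taxa x {self.n_partitions} "
            f"partitions, {100 * self.missing_fraction:.1f}% missing)"
        )


# ---------------------------------------------------------------------------
# Bins
# ---------------------------------------------------------------------------


class BinLabel(enum.Enum):
    """Shared-partition-tree bins.

    ``NO_PT`` is exactly 0% shared, ``FULL_TERRACE`` exactly 100%; ``PTq``
    covers the half-open interval ((q-1)/10, q/10] for q = 1..9 and PT10
    the open interval (90%, 100%).
    """

    NO_PT = "No PT"
    PT1 = "PT1"
    PT2 = "PT2"
    PT3 = "PT3"
    PT4 = "PT4"
    PT5 = "PT5"
    PT6 = "PT6"
    PT7 = "PT7"
    PT8 = "PT8"
    PT9 = "PT9"
    PT10 = "PT10"
    FULL_TERRACE = "Full terrace"

    def __str__(self) -> str:
        return self.value


_PT_BINS = [
    BinLabel.PT1, BinLabel.PT2, BinLabel.PT3, BinLabel.PT4, BinLabel.PT5,
    BinLabel.PT6, BinLabel.PT7, BinLabel.PT8, BinLabel.PT9, BinLabel.PT10,
]


def classify_bin(shared: int, total: int) -> BinLabel:
    """Bin a shared count by exact integer arithmetic (no floating point).

    ``PTq`` holds fractions in ((q-1)/10, q/10], decided by comparing
    ``10 * shared`` against ``q * total``.
    """
    if total <= 0:
        raise ValueError("total number of partitions must be positive")
    if not 0 <= shared <= total:
        raise ValueError("shared count out of range")
    if shared == 0:
        return BinLabel.NO_PT
    if shared == total:
        return BinLabel.FULL_TERRACE
    q = -(-10 * shared // total)  # ceil(10 * shared / total)
    return _PT_BINS[q - 1]


# ---------------------------------------------------------------------------
# Pairwise comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairComparison:
    """Which partition trees two species trees share."""

    shared_count: int
    total_partitions: int
    per_partition: tuple[bool, ...]  # True = induced trees identical
    reasons: tuple[Reason, ...] = ()

    @property
    def fraction(self) -> float:
        return self.shared_count / self.total_partitions

    @property
    def bin(self) -> BinLabel:
        return classify_bin(self.shared_count, self.total_partitions)

    @property
    def is_full_terrace(self) -> bool:
        return self.shared_count == self.total_partitions


def _check_tree_vs_coverage(tree: PhyloTree, cov: CoverageMatrix) -> None:
    if tree.taxa != cov.taxa:
        raise TreeError("tree and coverage matrix use different taxon indices")
    covered = 0
    for j in range(cov.n_partitions):
        covered |= cov.y_mask(j)
    if covered & ~tree.leaf_mask:
        missing = cov.taxa.labels_of(covered & ~tree.leaf_mask)
        raise TreeError(f"taxa covered by partitions but absent from tree: {missing}")


def compare_trees(
    t1: PhyloTree, t2: PhyloTree, cov: CoverageMatrix
) -> PairComparison:
    """Reference (slow) comparison: restrict both trees to every partition's
    taxon set and test topological identity."""
    _check_tree_vs_coverage(t1, cov)
    _check_tree_vs_coverage(t2, cov)
    if t1.leaf_mask != t2.leaf_mask:
        raise TreeError("trees must share one leaf set")
    shared_flags = []
    for j in range(cov.n_partitions):
        y = cov.y_mask(j)
        shared_flags.append(trees_equivalent(restrict(t1, y), restrict(t2, y)))
    shared = sum(shared_flags)
    return PairComparison(
        shared_count=shared,
        total_partitions=cov.n_partitions,
        per_partition=tuple(shared_flags),
    )


def compare_trees_fast(
    t: PhyloTree, move: Move, cov: CoverageMatrix
) -> PairComparison:
    """Compare ``t`` with ``apply(t, move)`` via the terrace predicates,
    never building a restricted tree.  Identical in result to
    :func:`compare_trees` on the applied pair."""
    _check_tree_vs_coverage(t, cov)
    flags = []
    reasons = []
    for j in range(cov.n_partitions):
        report = changes_partition(move, cov.y_mask(j), cov.partitions[j])
        flags.append(not report.changed)
        reasons.append(report.reason)
    shared = sum(flags)
    return PairComparison(
        shared_count=shared,
        total_partitions=cov.n_partitions,
        per_partition=tuple(flags),
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# NNI neighborhood sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeighborhoodSummary:
    """Bin histogram of one tree's NNI neighborhood under a coverage."""

    tree_id: str
    neighborhood_size: int
    bin_counts: dict[BinLabel, int]
    mean_shared_fraction: float

    @property
    def bin_percent(self) -> dict[BinLabel, float]:
        return {
            b: 100.0 * c / self.neighborhood_size
            for b, c in self.bin_counts.items()
        }


def iter_neighborhood(
    t: PhyloTree, cov: CoverageMatrix
) -> Iterator[tuple[Move, PairComparison]]:
    """Stream (move, comparison) for every NNI neighbor of ``t``, one at a
    time (memory stays flat on large trees)."""
    for move in enumerate_nni_moves(t):
        yield move, compare_trees_fast(t, move, cov)


def nni_neighborhood_summary(
    t: PhyloTree, cov: CoverageMatrix, tree_id: str = "tree"
) -> NeighborhoodSummary:
    """Sweep the full NNI neighborhood (2(n-3) trees) and bin each neighbor
    by its shared-partition-tree fraction."""
    counts = {b: 0 for b in BinLabel}
    fractions = []
    size = 0
    for _move, cmp_ in iter_neighborhood(t, cov):
        counts[cmp_.bin] += 1
        fractions.append(cmp_.fraction)
        size += 1
    if size == 0:
        raise TreeError("tree has no NNI neighborhood (fewer than 4 leaves)")
    return NeighborhoodSummary(
        tree_id=tree_id,
        neighborhood_size=size,
        bin_counts=counts,
        mean_shared_fraction=float(np.mean(fractions)),
    )


def savings_estimate(summary: NeighborhoodSummary) -> float:
    """Potential computational savings, in percent: the mean fraction of
    partition trees shared between the tree and its NNI neighbors
    (partitions weighted equally)."""
    return 100.0 * summary.mean_shared_fraction


def aggregate_summaries(
    summaries: Sequence[NeighborhoodSummary],
) -> pd.DataFrame:
    """Mean bin percentages over several trees' neighborhoods.

    Reports both weightings -- ``per_tree`` (each neighborhood's percentage
    averaged with equal weight) and ``per_neighbor`` (all neighbors pooled)
    -- since they differ when neighborhood sizes differ.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")
    rows = {}
    total_neighbors = sum(s.neighborhood_size for s in summaries)
    for b in BinLabel:
        per_tree = float(np.mean([s.bin_percent[b] for s in summaries]))
        pooled = 100.0 * sum(s.bin_counts[b] for s in summaries) / total_neighbors
        rows[str(b)] = {"per_tree": per_tree, "per_neighbor": pooled}
    return pd.DataFrame(rows).T


def neighborhood_report_frame(
    t: PhyloTree, cov: CoverageMatrix
) -> pd.DataFrame:
    """Per-neighbor TSV-ready table: move descriptor, shared count, total,
    fraction and bin."""
    taxa = t.taxa
    records = []
    for move, cmp_ in iter_neighborhood(t, cov):
        records.append(
            {
                "edge": "|".join(move.edge.smaller_side_labels(taxa)),
                "exchange": move.exchange.value,
                "shared": cmp_.shared_count,
                "total": cmp_.total_partitions,
                "fraction": cmp_.fraction,
                "bin": str(cmp_.bin),
            }
        )
    return pd.DataFrame.from_records(records)
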
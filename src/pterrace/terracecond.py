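"""Fast change/no-change predicates for induced partition trees.

Given a rearrangement of the species tree ``T`` and a partition covering the
taxa ``Y``, these predicates decide -- by bit-set intersection tests alone,
without ever building a restricted tree -- whether the induced partition
tree ``T|Y`` is topologically changed by the move:

* NNI around an edge with incident subtree taxon sets ``A, B, C, D``
  changes ``T|Y`` iff ``Y`` has a representative in each of the four sets.
* SPR pruning ``A`` across path subtrees ``B_1..B_n`` changes ``T|Y`` iff
  ``Y`` meets ``A`` and at least three of the ``B_i``.
* TBR across ``B_1..B_n`` / ``C_1..C_m`` changes ``T|Y`` iff ``Y`` meets at
  least one subtree on one side and at least three on the other.

The rationale: the move only rewrites path/central splits, and each of those
intersected with ``Y`` collapses onto a split shared by both induced trees
unless ``T|Y`` retains a genuine quartet around the rearranged edge(s).
When the predicate fires for SPR or TBR, the species-tree move maps to a
concrete induced move on ``T|Y`` whose prune/regraft (or cut/reconnect)
edges are reported as splits of the restricted taxon set; the reattachment
index is ``k = max{i : B_i & Y != 0}`` (and ``h`` likewise on the C side).

The restricted-tree route exists in the test suite as the brute-force
oracle; production code never takes it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .rearrange import (
    Move,
    NNIMove,
    SPRMove,
    TBRMove,
    apply_spr,
    apply_tbr,
    build_spr_move,
    build_tbr_move,
)
from .treecore import PhyloTree, Split, TreeError

__all__ = [
    "Reason",
    "InducedSPR",
    "InducedTBR",
    "PartitionChangeReport",
    "nni_changes_partition",
    "spr_changes_partition",
    "tbr_changes_partition",
    "changes_partition",
    "induced_spr_move",
    "induced_tbr_move",
    "edge_affects_partition",
]


class Reason(enum.Enum):
    """Why a partition tree was (or was not) changed by a move."""

    CHANGED = "changed"
    TOO_FEW_TAXA = "too_few_taxa"          # |Y| <= 3: no internal split exists
    EMPTY_INTERSECTION = "empty_intersection"  # a required subtree misses Y
    NO_QUARTET = "no_quartet"              # too few path subtrees represented

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class InducedSPR:
    """The SPR induced on ``T|Y`` by an SPR on ``T`` (when it changes it)."""

    prune_edge: Split     # A&Y | (B_1+..+B_n)&Y
    regraft_edge: Split   # B_k&Y | rest, k = max represented B index
    k: int                # 1-based index of the regraft path subtree


@dataclass(frozen=True)
class InducedTBR:
    """The TBR induced on ``T|Y`` by a TBR on ``T`` (when it changes it).

    When only one subtree of a side is represented, the corresponding
    reconnect split coincides with the cut split: the whole side component
    reattaches at its original junction and the induced move degenerates to
    an SPR (or NNI) on ``T|Y``.
    """

    cut_edge: Split
    reconnect_b: Split
    reconnect_c: Split
    k: int
    h: int


@dataclass(frozen=True)
class PartitionChangeReport:
    """Per-partition outcome of a species-tree rearrangement."""

    partition_id: str
    changed: bool
    reason: Reason
    induced_move: Optional[InducedSPR | InducedTBR] = None

    def __post_init__(self):
        if self.changed != (self.reason is Reason.CHANGED):
            raise ValueError("reason inconsistent with changed flag")


def _count_nonempty(masks, y_mask: int) -> int:
    return sum(1 for m in masks if m & y_mask)


def nni_changes_partition(
    move: NNIMove, y_mask: int, partition_id: str = ""
) -> PartitionChangeReport:
    """Does this NNI change the partition tree of taxa ``y_mask``?

    Changed iff all four of ``A, B, C, D`` intersect ``Y``; in that case the
    induced trees differ by RF 2 (the central quartet survives restriction),
    otherwise by RF 0.
    """
    if y_mask.bit_count() <= 3:
        return PartitionChangeReport(partition_id, False, Reason.TOO_FEW_TAXA)
    if all(m & y_mask for m in (move.a, move.b, move.c, move.d)):
        return PartitionChangeReport(partition_id, True, Reason.CHANGED)
    return PartitionChangeReport(partition_id, False, Reason.EMPTY_INTERSECTION)


def spr_changes_partition(
    move: SPRMove, y_mask: int, partition_id: str = ""
) -> PartitionChangeReport:
    """Does this SPR change the partition tree of taxa ``y_mask``?

    Changed iff ``A`` and at least three of the path subtrees ``B_1..B_n``
    are represented in ``Y``; the induced move is then attached to the
    report.
    """
    if y_mask.bit_count() <= 3:
        return PartitionChangeReport(partition_id, False, Reason.TOO_FEW_TAXA)
    if not move.a & y_mask:
        return PartitionChangeReport(partition_id, False, Reason.EMPTY_INTERSECTION)
    if _count_nonempty(move.path, y_mask) < 3:
        return PartitionChangeReport(partition_id, False, Reason.NO_QUARTET)
    return PartitionChangeReport(
        partition_id, True, Reason.CHANGED, induced_move=induced_spr_move(move, y_mask)
    )


def tbr_changes_partition(
    move: TBRMove, y_mask: int, partition_id: str = ""
) -> PartitionChangeReport:
    """Does this TBR change the partition tree of taxa ``y_mask``?

    Changed iff ``Y`` is represented in at least one subtree on one side of
    the bisection and at least three on the other (1+3); the symmetric 2+2
    configuration leaves the induced tree unchanged.
    """
    if y_mask.bit_count() <= 3:
        return PartitionChangeReport(partition_id, False, Reason.TOO_FEW_TAXA)
    nb = _count_nonempty(move.b_path, y_mask)
    nc = _count_nonempty(move.c_path, y_mask)
    if nb == 0 or nc == 0:
        return PartitionChangeReport(partition_id, False, Reason.EMPTY_INTERSECTION)
    if (nb >= 3 and nc >= 1) or (nb >= 1 and nc >= 3):
        return PartitionChangeReport(
            partition_id,
            True,
            Reason.CHANGED,
            induced_move=induced_tbr_move(move, y_mask),
        )
    return PartitionChangeReport(partition_id, False, Reason.NO_QUARTET)


def changes_partition(
    move: Move, y_mask: int, partition_id: str = ""
) -> PartitionChangeReport:
    """Dispatch on move kind."""
    if isinstance(move, NNIMove):
        return nni_changes_partition(move, y_mask, partition_id)
    if isinstance(move, SPRMove):
        return spr_changes_partition(move, y_mask, partition_id)
    if isinstance(move, TBRMove):
        return tbr_changes_partition(move, y_mask, partition_id)
    raise TypeError(f"not a move: {move!r}")


def induced_spr_move(move: SPRMove, y_mask: int) -> InducedSPR:
    """Map a changing SPR on ``T`` to the SPR it induces on ``T|Y``.

    Prune edge: ``A&Y | (B_1+..+B_n)&Y``; regraft edge:
    ``B_k&Y | ((union of other B_i) + A)&Y`` with ``k`` the largest index of
    a represented path subtree.
    """
    a_y = move.a & y_mask
    b_union = 0
    for m in move.path:
        b_union |= m
    b_y = b_union & y_mask
    if not a_y or _count_nonempty(move.path, y_mask) < 3:
        raise TreeError("induced move requested for an unchanged partition")
    k = max(i for i, m in enumerate(move.path, start=1) if m & y_mask)
    bk_y = move.path[k - 1] & y_mask
    universe = a_y | b_y
    return InducedSPR(
        prune_edge=Split(a_y, universe),
        regraft_edge=Split(bk_y, universe),
        k=k,
    )


def induced_tbr_move(move: TBRMove, y_mask: int) -> InducedTBR:
    """Map a changing TBR on ``T`` to the TBR it induces on ``T|Y``.

    Cut edge: ``(B_1+..+B_n)&Y | (C_1+..+C_m)&Y``; reconnect edges:
    ``B_k&Y | rest`` and ``C_h&Y | rest`` with ``k, h`` the largest
    represented indices on each side.
    """
    nb = _count_nonempty(move.b_path, y_mask)
    nc = _count_nonempty(move.c_path, y_mask)
    if nb == 0 or nc == 0 or not ((nb >= 3 and nc >= 1) or (nb >= 1 and nc >= 3)):
        raise TreeError("induced move requested for an unchanged partition")
    b_union = 0
    for m in move.b_path:
        b_union |= m
    c_union = 0
    for m in move.c_path:
        c_union |= m
    b_y, c_y = b_union & y_mask, c_union & y_mask
    universe = b_y | c_y
    k = max(i for i, m in enumerate(move.b_path, start=1) if m & y_mask)
    h = max(j for j, m in enumerate(move.c_path, start=1) if m & y_mask)
    return InducedTBR(
        cut_edge=Split(b_y, universe),
        reconnect_b=Split(move.b_path[k - 1] & y_mask, universe),
        reconnect_c=Split(move.c_path[h - 1] & y_mask, universe),
        k=k,
        h=h,
    )


def apply_induced_move(
    restricted: PhyloTree, induced: InducedSPR | InducedTBR
) -> PhyloTree:
    """Apply an induced-move descriptor to the restricted tree ``T|Y``.

    For a changing move this reproduces ``T_move|Y`` exactly (RF 0).  A
    degenerate induced TBR whose reconnect split on one side equals the cut
    split (only one subtree of that side represented in ``Y``) collapses to
    the SPR that prunes the *other* side's component.
    """
    if isinstance(induced, InducedSPR):
        move = build_spr_move(restricted, induced.prune_edge, induced.regraft_edge)
        return apply_spr(restricted, move)
    if isinstance(induced, InducedTBR):
        cut, rb, rc = induced.cut_edge, induced.reconnect_b, induced.reconnect_c
        if rb == cut and rc == cut:  # pragma: no cover - excluded by predicate
            raise TreeError("identity induced move")
        if rb == cut:
            # B component reattaches whole: SPR pruning the B side onto rc
            move = build_spr_move(restricted, cut, rc)
            return apply_spr(restricted, move)
        if rc == cut:
            move = build_spr_move(restricted, cut, rb)
            return apply_spr(restricted, move)
        move = build_tbr_move(restricted, cut, rb, rc)
        return apply_tbr(restricted, move)
    raise TypeError(f"not an induced move: {induced!r}")


def edge_affects_partition(edge_split: Split, y_mask: int) -> bool:
    """Does optimizing this species-tree edge affect the partition at all?

    False iff one side of the edge's split has an empty intersection with
    ``Y`` -- the edge then has no counterpart on ``T|Y``, so (under a linked
    edge-length model) its length does not enter that partition's
    likelihood.
    """
    return bool(edge_split.side_a & y_mask) and bool(edge_split.side_b & y_mask)
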
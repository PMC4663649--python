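"""Unrooted binary leaf-labeled trees, splits, RF distance and restriction.

The objects here are the vocabulary of terrace analysis: a species tree on a
taxon set ``X``, the split (bipartition) induced by each edge, the
Robinson--Foulds (RF) distance as the size of the symmetric difference of two
trees' split sets, and the induced subtree ``T|Y`` obtained by pruning a tree
down to the taxa ``Y`` covered by one data partition.

Splits are stored as integer bit-vectors over a fixed :class:`TaxonIndex`, so
that set intersections and emptiness tests -- the workhorses of the partial
terrace predicates -- are single machine operations.  The canonical side of a
split is the side that does *not* contain the lowest-ranked leaf present in
the tree, which makes ``A|B`` and ``B|A`` compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "LeafSetMismatchError",
    "TaxonIndex",
    "Split",
    "SplitSet",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "splits_of",
    "rf_distance",
    "trees_equivalent",
    "restrict",
]


class TreeError(ValueError):
    """Invalid tree structure or tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class LeafSetMismatchError(TreeError):
    """Operation requires two trees on the identical leaf set."""


# ---------------------------------------------------------------------------
# Taxa and splits
# ---------------------------------------------------------------------------


class TaxonIndex:
    """Immutable ordered register of taxon labels.

    All splits and coverage rows of one analysis refer to the same index, so
    a taxon subset is just an integer whose bit ``i`` flags the taxon of rank
    ``i``.
    """

    __slots__ = ("_names", "_position", "full_mask")

    def __init__(self, names: Iterable[str]):
        names = tuple(names)
        if not names:
            raise TreeError("TaxonIndex requires at least one label")
        for name in names:
            if not isinstance(name, str) or not name:
                raise TreeError(f"invalid taxon label: {name!r}")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate taxon labels: {dupes}")
        self._names = names
        self._position = {name: i for i, name in enumerate(names)}
        self.full_mask = (1 << len(names)) - 1

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[str]:
        return iter(self._names)

    def __contains__(self, label: str) -> bool:
        return label in self._position

    def rank(self, label: str) -> int:
        try:
            return self._position[label]
        except KeyError:
            raise TreeError(f"unknown taxon label: {label!r}") from None

    def label(self, rank: int) -> str:
        return self._names[rank]

    def mask_of(self, labels: Iterable[str]) -> int:
        """Bit-vector of a set of labels."""
        mask = 0
        for lab in labels:
            mask |= 1 << self.rank(lab)
        return mask

    def labels_of(self, mask: int) -> tuple[str, ...]:
        """Labels flagged in ``mask``, in rank order."""
        return tuple(self._names[i] for i in _iter_bits(mask))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"TaxonIndex({len(self)} taxa)"

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonIndex) and self._names == other._names

    def __hash__(self) -> int:
        return hash(self._names)


def _iter_bits(mask: int) -> Iterator[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


@dataclass(frozen=True)
class Split:
    """A bipartition ``A|B`` of the leaves of one tree.

    ``mask`` is the canonical side: the side not containing the
    lowest-ranked leaf of ``universe`` (the tree's full leaf set as a
    bit-vector).  Two splits are equal iff they bipartition the same leaf
    universe the same way, regardless of which side was supplied.
    """

    mask: int
    universe: int

    def __post_init__(self):
        if self.mask & ~self.universe:
            raise TreeError("split side is not a subset of the leaf universe")
        if self.mask == 0 or self.mask == self.universe:
            raise TreeError("both sides of a split must be non-empty")
        low = self.universe & -self.universe
        if self.mask & low:
            object.__setattr__(self, "mask", self.universe ^ self.mask)

    @property
    def side_a(self) -> int:
        """Canonical side (excludes the lowest-ranked leaf)."""
        return self.mask

    @property
    def side_b(self) -> int:
        """Complementary side (contains the lowest-ranked leaf)."""
        return self.universe ^ self.mask

    @property
    def is_trivial(self) -> bool:
        """True iff one side is a single taxon."""
        return self.mask.bit_count() == 1 or self.side_b.bit_count() == 1

    def restrict(self, y_mask: int) -> Optional["Split"]:
        """Induced split on the taxon subset ``y_mask``.

        Returns None when either side has an empty intersection with ``Y``
        (the edge then has no counterpart on the induced tree).
        """
        a = self.mask & y_mask
        b = self.side_b & y_mask
        if a == 0 or b == 0:
            return None
        return Split(a, a | b)

    def labels(self, taxa: TaxonIndex) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return taxa.labels_of(self.mask), taxa.labels_of(self.side_b)

    def smaller_side_labels(self, taxa: TaxonIndex) -> tuple[str, ...]:
        """Sorted labels of the smaller side (ties: canonical side).

        This is the identifier format used to address an edge from the
        outside (CLI, JSON move records).
        """
        a, b = self.mask, self.side_b
        side = a if a.bit_count() <= b.bit_count() else b
        return tuple(sorted(taxa.labels_of(side)))


@dataclass(frozen=True)
class SplitSet:
    """The collection ``Sigma(T)`` of splits of one tree."""

    splits: frozenset[Split]
    universe: int

    def __iter__(self) -> Iterator[Split]:
        return iter(self.splits)

    def __len__(self) -> int:
        return len(self.splits)

    def __contains__(self, split: Split) -> bool:
        return split in self.splits

    @property
    def nontrivial(self) -> frozenset[Split]:
        return frozenset(s for s in self.splits if not s.is_trivial)

    def symmetric_difference(self, other: "SplitSet") -> frozenset[Split]:
        return self.splits ^ other.splits


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class PhyloTree:
    """Unrooted binary tree with labeled leaves.

    Nodes are opaque integers.  ``taxa`` is the taxon universe of the
    analysis; the tree's leaves may be a subset of it (restriction returns
    trees on the same universe), tracked by ``leaf_mask``.  All topology
    comparisons go through split sets, never node identity.
    """

    __slots__ = ("taxa", "_adj", "_leaf_taxon", "_taxon_leaf", "_next_id", "_edge_len")

    def __init__(self, taxa: TaxonIndex):
        self.taxa = taxa
        self._adj: dict[int, set[int]] = {}
        self._leaf_taxon: dict[int, int] = {}
        self._taxon_leaf: dict[int, int] = {}
        self._next_id = 0
        self._edge_len: dict[frozenset[int], Optional[float]] = {}

    # -- construction -------------------------------------------------------

    def _new_node(self, taxon_rank: Optional[int] = None) -> int:
        node = self._next_id
        self._next_id += 1
        self._adj[node] = set()
        if taxon_rank is not None:
            if taxon_rank in self._taxon_leaf:
                raise TreeError(
                    f"duplicate leaf for taxon {self.taxa.label(taxon_rank)!r}"
                )
            self._leaf_taxon[node] = taxon_rank
            self._taxon_leaf[taxon_rank] = node
        return node

    def _add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        if v in self._adj[u]:
            raise TreeError("parallel edge")
        self._adj[u].add(v)
        self._adj[v].add(u)
        self._edge_len[frozenset((u, v))] = length

    def _remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self._edge_len.pop(frozenset((u, v)), None)

    def _remove_node(self, u: int) -> None:
        for v in list(self._adj[u]):
            self._remove_edge(u, v)
        del self._adj[u]
        rank = self._leaf_taxon.pop(u, None)
        if rank is not None:
            del self._taxon_leaf[rank]

    def _suppress_degree_two(self, u: int) -> None:
        """Replace a degree-2 node by a single edge, summing edge lengths."""
        p, q = sorted(self._adj[u])
        lp = self._edge_len.get(frozenset((u, p)))
        lq = self._edge_len.get(frozenset((u, q)))
        length = lp + lq if (lp is not None and lq is not None) else None
        self._remove_node(u)
        self._add_edge(p, q, length)

    def copy(self) -> "PhyloTree":
        t = PhyloTree(self.taxa)
        t._adj = {u: set(nbrs) for u, nbrs in self._adj.items()}
        t._leaf_taxon = dict(self._leaf_taxon)
        t._taxon_leaf = dict(self._taxon_leaf)
        t._next_id = self._next_id
        t._edge_len = dict(self._edge_len)
        return t

    # -- basic queries -------------------------------------------------------

    @property
    def leaf_mask(self) -> int:
        mask = 0
        for rank in self._taxon_leaf:
            mask |= 1 << rank
        return mask

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_taxon)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self._edge_len)

    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.taxa.label(r) for r in self._taxon_leaf))

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    def edges(self) -> Iterator[tuple[int, int]]:
        for e in self._edge_len:
            u, v = sorted(e)
            yield u, v

    def is_leaf(self, node: int) -> bool:
        return node in self._leaf_taxon

    def is_binary(self) -> bool:
        """Every internal node has degree exactly 3 (a leaf: degree 1)."""
        return all(
            len(nbrs) == (1 if u in self._leaf_taxon else 3)
            for u, nbrs in self._adj.items()
        ) or self.n_leaves <= 2

    def validate(self, require_binary: bool = True) -> None:
        n = self.n_leaves
        if n == 0:
            raise TreeError("tree has no leaves")
        # connectivity
        seen = self._component(next(iter(self._adj)))
        if len(seen) != self.n_nodes:
            raise TreeError("tree is disconnected")
        if require_binary and n >= 3:
            for u, nbrs in self._adj.items():
                want = 1 if u in self._leaf_taxon else 3
                if len(nbrs) != want:
                    raise TreeError(
                        f"node of degree {len(nbrs)} (expected {want}): "
                        "tree is not an unrooted binary tree"
                    )
            if self.n_edges != 2 * n - 3:
                raise TreeError("edge count violates 2n-3")

    def _component(self, start: int, banned_edge: Optional[frozenset[int]] = None) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self._adj[u]:
                if banned_edge is not None and frozenset((u, v)) == banned_edge:
                    continue
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    # -- splits --------------------------------------------------------------

    def side_mask(self, u: int, v: int) -> int:
        """Taxon bit-vector of the component containing ``v`` when edge
        ``(u, v)`` is cut."""
        nodes = self._component(v, banned_edge=frozenset((u, v)))
        mask = 0
        for node in nodes:
            rank = self._leaf_taxon.get(node)
            if rank is not None:
                mask |= 1 << rank
        return mask

    def edge_masks(self) -> dict[tuple[int, int], int]:
        """For every edge ``(u, v)`` (both orientations) the taxon mask of
        the side containing ``v``.  One post-order pass."""
        if self.n_nodes == 1:
            return {}
        root = next(iter(self._adj))
        masks: dict[tuple[int, int], int] = {}
        full = self.leaf_mask
        # iterative post-order
        stack: list[tuple[int, int, bool]] = [
            (root, child, False) for child in self._adj[root]
        ]
        while stack:
            parent, node, processed = stack.pop()
            if processed:
                rank = self._leaf_taxon.get(node)
                mask = 0 if rank is None else (1 << rank)
                for child in self._adj[node]:
                    if child != parent:
                        mask |= masks[(node, child)]
                masks[(parent, node)] = mask
            else:
                stack.append((parent, node, True))
                for child in self._adj[node]:
                    if child != parent:
                        stack.append((node, child, False))
        rank = self._leaf_taxon.get(root)
        root_bit = 0 if rank is None else (1 << rank)
        for child in self._adj[root]:
            masks[(child, root)] = full ^ masks[(root, child)]
        # fill reverse orientations
        for (u, v), m in list(masks.items()):
            masks[(v, u)] = full ^ m
        return masks

    def split_for_edge(self, u: int, v: int) -> Split:
        return Split(self.side_mask(u, v), self.leaf_mask)

    def find_edge(self, split: Split) -> tuple[int, int]:
        """Locate the edge realizing ``split``; returns ``(u, v)`` with ``v``
        on the canonical side.  Raises TreeError when absent."""
        if split.universe != self.leaf_mask:
            raise TreeError("split universe does not match the tree's leaf set")
        masks = self.edge_masks()
        for (u, v), m in masks.items():
            if m == split.mask:
                return u, v
        raise TreeError("no edge of the tree realizes this split")

    def interior_edges(self) -> Iterator[tuple[int, int]]:
        for u, v in self.edges():
            if not self.is_leaf(u) and not self.is_leaf(v):
                yield u, v

    # -- misc ----------------------------------------------------------------

    def leaf_for_taxon(self, rank: int) -> int:
        return self._taxon_leaf[rank]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PhyloTree({self.n_leaves} leaves, {self.n_edges} edges)"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(
    text: str,
    taxa: Optional[TaxonIndex] = None,
    allow_polytomies: bool = False,
) -> PhyloTree:
    """Parse a single Newick statement into an unrooted tree.

    A tree rooted at a bifurcation is unrooted by suppressing the degree-2
    root.  Edge lengths are parsed and kept for round-tripping but are
    ignored by every topology comparison.  When ``taxa`` is given, leaf
    labels must be a subset of it and the returned tree shares that taxon
    universe; otherwise a fresh :class:`TaxonIndex` is built from the leaf
    labels in sorted order.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    dleaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [
        (lf.taxon.label if lf.taxon is not None else lf.label) for lf in dleaves
    ]
    if any(lab is None or lab == "" for lab in labels):
        raise NewickParseError("tree contains an unlabeled leaf")
    if len(set(labels)) != len(labels):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    if taxa is None:
        taxa = TaxonIndex(sorted(labels))
    else:
        for lab in labels:
            if lab not in taxa:
                raise TreeError(f"leaf label {lab!r} not in the supplied TaxonIndex")

    tree = PhyloTree(taxa)

    def build(dnode, parent: Optional[int]) -> int:
        children = dnode.child_nodes()
        if not children:
            lab = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = tree._new_node(taxa.rank(lab))
        else:
            node = tree._new_node()
        if parent is not None:
            tree._add_edge(parent, node, dnode.edge.length)
        for child in children:
            build(child, node)
        return node

    root = build(dtree.seed_node, None)

    # Suppress a degree-2 root (input rooted at a bifurcation), unless the
    # tree is so small the root is a leaf or the whole tree.
    if tree.degree(root) == 2 and root not in tree._leaf_taxon:
        tree._suppress_degree_two(root)

    if tree.n_leaves >= 3 and not allow_polytomies and not tree.is_binary():
        raise TreeError(
            "tree contains polytomies; pass allow_polytomies=True to accept"
        )
    tree.validate(require_binary=not allow_polytomies)
    return tree


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.+|-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree, lengths: bool = False) -> str:
    """Deterministic Newick serialization.

    The output is rooted at the internal node adjacent to the lowest-ranked
    leaf (for >= 3 leaves) and children are ordered by the smallest taxon
    rank contained in their subtree, so equivalent trees on the same leaf
    set serialize identically.
    """
    n = tree.n_leaves
    taxa = tree.taxa
    if n == 0:
        raise TreeError("cannot serialize an empty tree")
    if n == 1:
        (leaf,) = tree._leaf_taxon
        return _quote_label(taxa.label(tree._leaf_taxon[leaf])) + ";"
    masks = tree.edge_masks()

    def fmt_len(u: int, v: int) -> str:
        if not lengths:
            return ""
        ln = tree._edge_len.get(frozenset((u, v)))
        return "" if ln is None else f":{ln:g}"

    def render(parent: int, node: int) -> str:
        if tree.is_leaf(node):
            return _quote_label(taxa.label(tree._leaf_taxon[node])) + fmt_len(parent, node)
        kids = sorted(
            (v for v in tree._adj[node] if v != parent),
            key=lambda v: _lowest_bit(masks[(node, v)]),
        )
        inner = ",".join(render(node, v) for v in kids)
        return f"({inner})" + fmt_len(parent, node)

    if n == 2:
        a, b = sorted(tree._leaf_taxon.values())
        la, lb = tree.leaf_for_taxon(a), tree.leaf_for_taxon(b)
        return f"({_quote_label(taxa.label(a))},{render(la, lb)});"

    lowest_rank = _lowest_bit(tree.leaf_mask)
    anchor_leaf = tree.leaf_for_taxon(lowest_rank)
    root = next(iter(tree._adj[anchor_leaf]))
    kids = sorted(
        tree._adj[root],
        key=lambda v: _lowest_bit(masks[(root, v)]),
    )
    inner = ",".join(render(root, v) for v in kids)
    return f"({inner});"


def _lowest_bit(mask: int) -> int:
    return (mask & -mask).bit_length() - 1


# ---------------------------------------------------------------------------
# Split extraction, RF distance, restriction
# ---------------------------------------------------------------------------


def splits_of(tree: PhyloTree) -> SplitSet:
    """One split per edge of the tree (``Sigma(T)``)."""
    if tree.n_leaves < 2:
        return SplitSet(frozenset(), tree.leaf_mask)
    full = tree.leaf_mask
    masks = tree.edge_masks()
    splits = set()
    for u, v in tree.edges():
        splits.add(Split(masks[(u, v)], full))
    return SplitSet(frozenset(splits), full)


def _check_same_leaves(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.taxa != t2.taxa or t1.leaf_mask != t2.leaf_mask:
        raise LeafSetMismatchError(
            "trees must be on the identical leaf set for RF comparison"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson--Foulds distance: ``|Sigma(T1) symdiff Sigma(T2)|``.

    Trivial splits are identical for trees on the same leaf set, so only
    internal splits can contribute to the symmetric difference.
    """
    _check_same_leaves(t1, t2)
    return len(splits_of(t1).symmetric_difference(splits_of(t2)))


def trees_equivalent(t1: PhyloTree, t2: PhyloTree) -> bool:
    """True iff the two trees have the same split collection (RF = 0).

    By the splits-equivalence theorem this is topological identity.  Trees
    with fewer than 4 leaves on the same leaf set are always equivalent.
    """
    return rf_distance(t1, t2) == 0


def restrict(tree: PhyloTree, y: Iterable[str] | int) -> PhyloTree:
    """Induced subtree ``T|Y``: prune leaves outside ``Y``, then suppress
    all degree-2 nodes.

    ``y`` is a taxon-label iterable or a bit-mask over the tree's taxon
    universe.  The result keeps the same :class:`TaxonIndex`, so splits of
    ``T|Y`` and of any other restriction to the same ``Y`` are directly
    comparable.  The split collection of the result equals
    ``{A&Y | B&Y : A|B in Sigma(T), both non-empty}`` (deduplicated).
    """
    y_mask = y if isinstance(y, int) else tree.taxa.mask_of(y)
    if y_mask == 0:
        raise TreeError("restriction to an empty taxon set")
    if y_mask & ~tree.leaf_mask:
        missing = tree.taxa.labels_of(y_mask & ~tree.leaf_mask)
        raise TreeError(f"taxa not present in the tree: {missing}")

    t = tree.copy()
    drop = [
        leaf
        for leaf, rank in t._leaf_taxon.items()
        if not (y_mask >> rank) & 1
    ]
    for leaf in drop:
        t._remove_node(leaf)
    # iteratively clean: remove dangling internal nodes, suppress degree-2
    changed = True
    while changed:
        changed = False
        for node in list(t._adj):
            if node in t._leaf_taxon:
                continue
            deg = len(t._adj[node])
            if deg == 0:
                t._remove_node(node)
                changed = True
            elif deg == 1:
                t._remove_node(node)
                changed = True
            elif deg == 2:
                t._suppress_degree_two(node)
                changed = True
    return t
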
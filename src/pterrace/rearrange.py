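"""NNI, SPR and TBR rearrangements with resolved context subtrees.

Every move is a value object bound to one tree snapshot.  Besides the edges
it acts on, a move carries the taxon sets of the subtrees around those edges
(``A, B, C, D`` for an NNI; ``A, B_1..B_n`` for an SPR; ``B_1..B_n`` and
``C_1..C_m`` for a TBR).  These context sets determine, purely by split
algebra, which splits the move changes:

* an NNI around an interior edge replaces ``A|B <-> C|D`` context split
  ``A+B | C+D`` by ``A+D | B+C`` (or ``A+C | B+D``), so RF(T, T_NNI) = 2;
* an SPR pruning ``A`` and regrafting across path subtrees ``B_1..B_n``
  changes the n-2 path splits and creates one new edge: RF = 2(n-2);
* a TBR bisecting at ``e`` and reconnecting across ``B_1..B_n`` and
  ``C_1..C_m`` changes both paths but keeps ``e`` itself: RF = 2(n+m-4).

The same context sets feed the partial-terrace predicates in
:mod:`pterrace.terracecond`, which is why they are resolved eagerly here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator

from .treecore import PhyloTree, Split, TreeError

__all__ = [
    "InvalidMoveError",
    "StaleMoveError",
    "NNIExchange",
    "NNIMove",
    "SPRMove",
    "TBRMove",
    "enumerate_nni_moves",
    "resolve_nni_context",
    "apply_nni",
    "build_spr_move",
    "apply_spr",
    "enumerate_spr_moves",
    "build_tbr_move",
    "apply_tbr",
    "enumerate_tbr_moves",
    "apply_move",
    "predicted_rf",
    "predicted_split_changes",
]


class InvalidMoveError(TreeError):
    """Move cannot be built or applied (degenerate or ill-posed)."""


class StaleMoveError(InvalidMoveError):
    """Move refers to edges that the given tree does not have."""


class NNIExchange(enum.Enum):
    """Which opposite-endpoint subtree is exchanged with ``A`` (= e1 side)."""

    E1_E3 = "e1<->e3"  # swap A with C
    E1_E4 = "e1<->e4"  # swap A with D


# ---------------------------------------------------------------------------
# Move descriptors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NNIMove:
    """Nearest neighbor interchange around interior edge ``edge``.

    ``a, b, c, d`` are the taxon bit-masks of the four subtrees incident to
    the edge: ``a`` and ``b`` hang off one endpoint, ``c`` and ``d`` off the
    other.  Convention: the ``(a, b)`` endpoint is the one on the side of
    the edge containing the tree's lowest-ranked leaf, and within an
    endpoint the subtree with the smaller minimum rank comes first.
    """

    edge: Split
    exchange: NNIExchange
    a: int
    b: int
    c: int
    d: int

    @property
    def kind(self) -> str:
        return "NNI"

    @property
    def swapped_mask(self) -> int:
        """Mask of the subtree exchanged with ``a``."""
        return self.c if self.exchange is NNIExchange.E1_E3 else self.d


@dataclass(frozen=True)
class SPRMove:
    """Subtree pruning and regrafting.

    The subtree with taxon mask ``a`` (the component of ``prune_edge`` away
    from the regraft edge) is pruned and reattached onto ``regraft_edge``.
    ``path`` holds the taxon masks ``B_1..B_n`` of the subtrees hanging off
    the tree path from the attachment node to the regraft edge, in walk
    order; ``B_n`` is the component beyond the regraft edge.  ``n = len(path)``
    is at least 3 (n = 3 is the NNI-equivalent case).
    """

    prune_edge: Split
    regraft_edge: Split
    a: int
    path: tuple[int, ...]

    @property
    def kind(self) -> str:
        return "SPR"

    @property
    def n(self) -> int:
        return len(self.path)

    @property
    def is_nni_equivalent(self) -> bool:
        return self.n == 3


@dataclass(frozen=True)
class TBRMove:
    """Tree bisection and reconnection.

    The tree is cut at ``bisect_edge``; the two components are reconnected
    by a new edge joining a subdivision of ``reconnect_b`` (in the component
    holding path subtrees ``B_1..B_n``) with one of ``reconnect_c``
    (``C_1..C_m``).  ``n >= 2``, ``m >= 2`` and not both equal 2 (that would
    be the identity).  The bisection split itself is preserved by the move.
    """

    bisect_edge: Split
    reconnect_b: Split
    reconnect_c: Split
    b_path: tuple[int, ...]
    c_path: tuple[int, ...]

    @property
    def kind(self) -> str:
        return "TBR"

    @property
    def n(self) -> int:
        return len(self.b_path)

    @property
    def m(self) -> int:
        return len(self.c_path)

    @property
    def is_nni_equivalent(self) -> bool:
        return sorted((self.n, self.m)) == [2, 3]

    @property
    def is_spr_equivalent(self) -> bool:
        return min(self.n, self.m) == 2


Move = NNIMove | SPRMove | TBRMove


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------


def _nni_context_at(tree: PhyloTree, u: int, v: int, masks) -> tuple[int, int, int, int]:
    """Context masks (a, b, c, d) for interior edge (u, v).

    The endpoint whose side contains the lowest-ranked leaf of the tree
    hosts (a, b).
    """
    full = tree.leaf_mask
    low_bit = full & -full
    if masks[(v, u)] & low_bit:
        ab_node, cd_node = u, v
    else:
        ab_node, cd_node = v, u
    ab_sides = sorted(
        (masks[(ab_node, w)] for w in tree._adj[ab_node] if w != cd_node),
        key=lambda m: (m & -m),
    )
    cd_sides = sorted(
        (masks[(cd_node, w)] for w in tree._adj[cd_node] if w != ab_node),
        key=lambda m: (m & -m),
    )
    a, b = ab_sides
    c, d = cd_sides
    return a, b, c, d


def resolve_nni_context(tree: PhyloTree, edge: Split) -> tuple[int, int, int, int]:
    """Taxon masks ``(A, B, C, D)`` of the four subtrees around an interior
    edge, by the documented endpoint/ordering convention."""
    u, v = tree.find_edge(edge)
    if tree.is_leaf(u) or tree.is_leaf(v):
        raise InvalidMoveError("NNI context requires an interior edge")
    return _nni_context_at(tree, u, v, tree.edge_masks())


def enumerate_nni_moves(tree: PhyloTree) -> list[NNIMove]:
    """The 2(n-3) NNI moves of a binary tree: two per interior edge."""
    if tree.n_leaves < 4:
        return []
    masks = tree.edge_masks()
    full = tree.leaf_mask
    moves = []
    for u, v in tree.interior_edges():
        a, b, c, d = _nni_context_at(tree, u, v, masks)
        edge = Split(masks[(u, v)], full)
        for exch in (NNIExchange.E1_E3, NNIExchange.E1_E4):
            moves.append(NNIMove(edge=edge, exchange=exch, a=a, b=b, c=c, d=d))
    return moves


def apply_nni(tree: PhyloTree, move: NNIMove) -> PhyloTree:
    """Return the tree with the two subtrees of the move exchanged.

    The input tree is never modified.
    """
    t = tree.copy()
    try:
        u, v = t.find_edge(move.edge)
    except TreeError as exc:
        raise StaleMoveError(str(exc)) from exc
    masks = t.edge_masks()

    def neighbor_with_mask(node: int, other: int, mask: int) -> int:
        for w in t._adj[node]:
            if w != other and masks[(node, w)] == mask:
                return w
        raise StaleMoveError("move context does not match the tree")

    # identify endpoints: (a, b) side vs (c, d) side
    if masks[(u, v)] | masks[(v, u)] != t.leaf_mask:
        raise StaleMoveError("edge masks inconsistent")
    if (move.a | move.b) == masks[(v, u)]:
        ab_node, cd_node = u, v
    elif (move.a | move.b) == masks[(u, v)]:
        ab_node, cd_node = v, u
    else:
        raise StaleMoveError("move context does not match the tree")
    a_root = neighbor_with_mask(ab_node, cd_node, move.a)
    swap_root = neighbor_with_mask(cd_node, ab_node, move.swapped_mask)
    t._remove_edge(ab_node, a_root)
    t._remove_edge(cd_node, swap_root)
    t._add_edge(ab_node, swap_root)
    t._add_edge(cd_node, a_root)
    return t


# ---------------------------------------------------------------------------
# Path decomposition shared by SPR and TBR
# ---------------------------------------------------------------------------


def _node_path(tree: PhyloTree, start: int, goal: int, avoid: int) -> list[int]:
    """Unique tree path start..goal not passing through node ``avoid``."""
    parent = {start: None}
    stack = [start]
    while stack:
        x = stack.pop()
        if x == goal:
            break
        for y in tree._adj[x]:
            if y == avoid or y in parent:
                continue
            parent[y] = x
            stack.append(y)
    if goal not in parent:
        raise InvalidMoveError("target edge unreachable on this side")
    path = [goal]
    while path[-1] != start:
        path.append(parent[path[-1]])
    path.reverse()
    return path


def _path_decomposition(
    tree: PhyloTree,
    start: int,
    avoid: int,
    target_u: int,
    target_v: int,
    masks,
) -> tuple[int, ...]:
    """Side-subtree masks ``B_1..B_n`` along the path from ``start`` to the
    target edge, avoiding node ``avoid``; ``B_n`` is the component beyond
    the target edge.

    ``start`` must be incident to the avoided node; ``n = len(result)`` is
    ``len(path) + 1`` where path runs from ``start`` to the nearer endpoint
    of the target edge.
    """
    # nearer endpoint of target edge
    try:
        path = _node_path(tree, start, target_u, avoid)
    except InvalidMoveError:
        path = None
    if path is not None and target_v in path:
        near, far = target_v, target_u
        path = path[: path.index(target_v) + 1]
    elif path is not None:
        near, far = target_u, target_v
    else:
        path = _node_path(tree, start, target_v, avoid)
        if target_u in path:
            near, far = target_u, target_v
            path = path[: path.index(target_u) + 1]
        else:
            near, far = target_v, target_u
    sides: list[int] = []
    for i, w in enumerate(path):
        banned = {avoid if i == 0 else path[i - 1]}
        if i + 1 < len(path):
            banned.add(path[i + 1])
        else:
            banned.add(far)
        rest = [x for x in tree._adj[w] if x not in banned]
        if len(rest) != 1:
            raise InvalidMoveError("path decomposition failed: tree not binary?")
        sides.append(masks[(w, rest[0])])
    sides.append(masks[(near, far)])
    return tuple(sides)


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------


def build_spr_move(tree: PhyloTree, prune_edge: Split, regraft_edge: Split) -> SPRMove:
    """Resolve an SPR move: prune the component of ``prune_edge`` away from
    ``regraft_edge``, regraft onto ``regraft_edge``.

    Raises :class:`InvalidMoveError` when the regraft edge is the prune edge
    itself or adjacent to the attachment node (identity placements, n < 3).
    """
    if prune_edge == regraft_edge:
        raise InvalidMoveError("regraft edge equals prune edge")
    try:
        pu, pv = tree.find_edge(prune_edge)
        ru, rv = tree.find_edge(regraft_edge)
    except TreeError as exc:
        raise StaleMoveError(str(exc)) from exc
    masks = tree.edge_masks()
    # orientation: A = side of prune_edge not containing the regraft edge
    pv_side = tree._component(pv, banned_edge=frozenset((pu, pv)))
    if ru in pv_side and rv in pv_side:
        att, a_root = pv, pu
    elif ru not in pv_side and rv not in pv_side:
        att, a_root = pu, pv
    else:
        raise InvalidMoveError("regraft edge is the prune edge itself")
    a_mask = masks[(att, a_root)]
    if {ru, rv} & {att}:
        raise InvalidMoveError(
            "regraft edge adjacent to the attachment node: identity move"
        )
    path = _path_decomposition(tree, att, a_root, ru, rv, masks)
    if len(path) < 3:
        raise InvalidMoveError("degenerate SPR (n < 3)")
    return SPRMove(
        prune_edge=prune_edge,
        regraft_edge=regraft_edge,
        a=a_mask,
        path=path,
    )


def apply_spr(tree: PhyloTree, move: SPRMove) -> PhyloTree:
    """Apply an SPR move, returning a new tree (input unmodified)."""
    t = tree.copy()
    try:
        pu, pv = t.find_edge(move.prune_edge)
        ru, rv = t.find_edge(move.regraft_edge)
    except TreeError as exc:
        raise StaleMoveError(str(exc)) from exc
    masks = t.edge_masks()
    if masks[(pu, pv)] == move.a:
        att, a_root = pu, pv
    elif masks[(pv, pu)] == move.a:
        att, a_root = pv, pu
    else:
        raise StaleMoveError("pruned-side mask does not match the tree")
    if att in (ru, rv):
        raise InvalidMoveError("regraft edge adjacent to attachment: identity")
    t._remove_edge(att, a_root)
    t._suppress_degree_two(att)
    # the regraft edge may have been re-formed by the suppression; relocate
    if rv not in t._adj.get(ru, ()):  # pragma: no cover - defensive
        raise StaleMoveError("regraft edge vanished during pruning")
    new = t._new_node()
    t._remove_edge(ru, rv)
    t._add_edge(ru, new)
    t._add_edge(new, rv)
    t._add_edge(new, a_root)
    return t


def enumerate_spr_moves(
    tree: PhyloTree, radius: int = 5
) -> Iterator[SPRMove]:
    """All SPR moves whose path parameter n satisfies ``3 <= n <= radius+1``.

    Tree searches in practice use short SPR; the radius cap keeps the
    enumeration near-linear per prune edge.
    """
    full = tree.leaf_mask
    masks = tree.edge_masks()
    edge_splits = [Split(masks[(u, v)], full) for u, v in tree.edges()]
    for prune in edge_splits:
        for regraft in edge_splits:
            if prune == regraft:
                continue
            try:
                move = build_spr_move(tree, prune, regraft)
            except InvalidMoveError:
                continue
            if move.n <= radius + 1:
                yield move


# ---------------------------------------------------------------------------
# TBR
# ---------------------------------------------------------------------------


def build_tbr_move(
    tree: PhyloTree,
    bisect_edge: Split,
    reconnect_b: Split,
    reconnect_c: Split,
) -> TBRMove:
    """Resolve a TBR move: cut ``bisect_edge``, reconnect the two components
    by joining subdivisions of ``reconnect_b`` and ``reconnect_c``.

    The B side is the component containing ``reconnect_b``.  Degenerate
    ``n = m = 2`` placements (both reconnect edges adjacent to the bisection
    endpoints) are rejected as the identity.
    """
    if bisect_edge in (reconnect_b, reconnect_c):
        raise InvalidMoveError("reconnect edge equals the bisection edge")
    try:
        eu, ev = tree.find_edge(bisect_edge)
        bu, bv = tree.find_edge(reconnect_b)
        cu, cv = tree.find_edge(reconnect_c)
    except TreeError as exc:
        raise StaleMoveError(str(exc)) from exc
    masks = tree.edge_masks()
    ev_side = tree._component(ev, banned_edge=frozenset((eu, ev)))

    def side_of(x, y):
        inside = (x in ev_side, y in ev_side)
        if inside == (True, True):
            return ev
        if inside == (False, False):
            return eu
        raise InvalidMoveError("reconnect edge equals the bisection edge")

    b_end = side_of(bu, bv)
    c_end = side_of(cu, cv)
    if b_end == c_end:
        raise InvalidMoveError(
            "reconnect edges must lie in the two different components"
        )
    b_start, c_start = b_end, c_end
    b_path = _path_decomposition(
        tree, b_start, ev if b_start == eu else eu, bu, bv, masks
    )
    c_path = _path_decomposition(
        tree, c_start, ev if c_start == eu else eu, cu, cv, masks
    )
    n, m = len(b_path), len(c_path)
    if n < 2 or m < 2:  # pragma: no cover - cannot occur on binary trees
        raise InvalidMoveError("degenerate TBR")
    if n == 2 and m == 2:
        raise InvalidMoveError(
            "both reconnect edges adjacent to the bisection endpoints: identity"
        )
    return TBRMove(
        bisect_edge=bisect_edge,
        reconnect_b=reconnect_b,
        reconnect_c=reconnect_c,
        b_path=b_path,
        c_path=c_path,
    )


def apply_tbr(tree: PhyloTree, move: TBRMove) -> PhyloTree:
    """Apply a TBR move, returning a new tree (input unmodified).

    The bisection split is preserved: it is realized by the new connecting
    edge.
    """
    t = tree.copy()
    try:
        eu, ev = t.find_edge(move.bisect_edge)
    except TreeError as exc:
        raise StaleMoveError(str(exc)) from exc
    masks = t.edge_masks()
    b_union = 0
    for mask in move.b_path:
        b_union |= mask
    if masks[(eu, ev)] == b_union:
        b_end, c_end = ev, eu
    elif masks[(ev, eu)] == b_union:
        b_end, c_end = eu, ev
    else:
        raise StaleMoveError("B-side mask does not match the tree")
    b_n = move.b_path[-1]
    c_m = move.c_path[-1]
    t._remove_edge(eu, ev)
    # the endpoints are suppressed below; keep a surviving node per component
    b_seed = next(iter(t._adj[b_end]))
    c_seed = next(iter(t._adj[c_end]))
    for node in (eu, ev):
        if len(t._adj[node]) == 2:
            t._suppress_degree_two(node)
        else:  # pragma: no cover - binary trees guarantee degree 3 endpoints
            raise StaleMoveError("unexpected degree after bisection")

    def subdivide_at(component_seed: int, far_mask: int) -> int:
        """Find the edge of the component whose far side is ``far_mask`` and
        subdivide it, returning the new node."""
        nodes = t._component(component_seed)
        for x in nodes:
            for y in t._adj[x]:
                if t.side_mask(x, y) == far_mask:
                    mid = t._new_node()
                    t._remove_edge(x, y)
                    t._add_edge(x, mid)
                    t._add_edge(mid, y)
                    return mid
        raise StaleMoveError("reconnect edge not found after bisection")

    nb = subdivide_at(b_seed, b_n)
    nc = subdivide_at(c_seed, c_m)
    t._add_edge(nb, nc)
    return t


def enumerate_tbr_moves(
    tree: PhyloTree, radius: int = 5
) -> Iterator[TBRMove]:
    """TBR moves with both path parameters capped: ``n, m <= radius + 1``."""
    full = tree.leaf_mask
    masks = tree.edge_masks()
    edge_splits = [Split(masks[(u, v)], full) for u, v in tree.edges()]
    for bisect in edge_splits:
        eu, ev = tree.find_edge(bisect)
        if tree.is_leaf(eu) or tree.is_leaf(ev):
            continue  # a pendant bisection has an empty side component
        ev_side = tree._component(ev, banned_edge=frozenset((eu, ev)))
        b_edges = [
            s
            for s in edge_splits
            if s != bisect and all(x in ev_side for x in tree.find_edge(s))
        ]
        c_edges = [
            s
            for s in edge_splits
            if s != bisect and all(x not in ev_side for x in tree.find_edge(s))
        ]
        for rb in b_edges:
            for rc in c_edges:
                try:
                    move = build_tbr_move(tree, bisect, rb, rc)
                except InvalidMoveError:
                    continue
                if move.n <= radius + 1 and move.m <= radius + 1:
                    yield move


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


def apply_move(tree: PhyloTree, move: Move) -> PhyloTree:
    if isinstance(move, NNIMove):
        return apply_nni(tree, move)
    if isinstance(move, SPRMove):
        return apply_spr(tree, move)
    if isinstance(move, TBRMove):
        return apply_tbr(tree, move)
    raise TypeError(f"not a move: {move!r}")


def predicted_rf(move: Move) -> int:
    """RF distance between a tree and its image under ``move``, from the
    closed forms: 2 for NNI, 2(n-2) for SPR, 2(n+m-4) for TBR."""
    if isinstance(move, NNIMove):
        return 2
    if isinstance(move, SPRMove):
        return 2 * (move.n - 2)
    if isinstance(move, TBRMove):
        return 2 * (move.n + move.m - 4)
    raise TypeError(f"not a move: {move!r}")


def predicted_split_changes(move: Move, universe: int) -> frozenset[Split]:
    """The predicted symmetric difference ``Sigma(T) symdiff Sigma(T_move)``.

    For an NNI this is the pair of central-edge splits before and after the
    exchange.  For SPR/TBR it is the before/after family of path-edge
    splits.
    """
    out: set[Split] = set()
    if isinstance(move, NNIMove):
        ab = move.a | move.b
        if move.exchange is NNIExchange.E1_E3:
            after = move.a | move.d
        else:
            after = move.a | move.c
        out.add(Split(ab, universe))
        out.add(Split(after, universe))
        return frozenset(out)
    if isinstance(move, SPRMove):
        b = move.path
        n = move.n
        prefix = 0
        prefixes = []
        for mask in b:
            prefix |= mask
            prefixes.append(prefix)
        for x in range(1, n - 1):  # e_x, x = 1..n-2
            out.add(Split(move.a | prefixes[x - 1], universe))
        for x in range(2, n + 0):  # e_x^SPR, x = 2..n-1
            out.add(Split(prefixes[x - 1], universe))
        return frozenset(out)
    if isinstance(move, TBRMove):
        bs, cs = move.b_path, move.c_path
        n, m = move.n, move.m
        b_union = 0
        b_pref = []
        for mask in bs:
            b_union |= mask
            b_pref.append(b_union)
        c_union = 0
        c_pref = []
        for mask in cs:
            c_union |= mask
            c_pref.append(c_union)
        c_all, b_all = c_pref[-1], b_pref[-1]
        for x in range(1, n - 1):
            out.add(Split(c_all | b_pref[x - 1], universe))
        for x in range(2, n):
            out.add(Split(b_pref[x - 1], universe))
        for y in range(1, m - 1):
            out.add(Split(b_all | c_pref[y - 1], universe))
        for y in range(2, m):
            out.add(Split(c_pref[y - 1], universe))
        return frozenset(out)
    raise TypeError(f"not a move: {move!r}")
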
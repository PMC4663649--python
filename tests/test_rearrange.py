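"""NNI/SPR/TBR enumeration, application, predicted RF and split changes."""

import numpy as np
import pytest

import pterrace as pt
from pterrace.rearrange import (
    InvalidMoveError,
    NNIExchange,
    StaleMoveError,
    enumerate_spr_moves,
    enumerate_tbr_moves,
    predicted_split_changes,
)
from pterrace.simulate import yule_harding_tree
from pterrace.treecore import Split

from conftest import random_spr, random_tbr, random_tree


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("newick, expected", [
    ("((a,b),(c,d));", 2),
    ("(a,b,c);", 0),
])
def test_nni_count_small(newick, expected):
    assert len(pt.enumerate_nni_moves(pt.parse_newick(newick))) == expected


def test_nni_neighborhood_size_and_distinctness(rng):
    for n in (5, 8, 10):
        t = yule_harding_tree(n, rng)
        moves = pt.enumerate_nni_moves(t)
        assert len(moves) == 2 * (n - 3)
        neighbors = [pt.apply_nni(t, m) for m in moves]
        for i, a in enumerate(neighbors):
            assert pt.rf_distance(t, a) == 2
            for b in neighbors[i + 1:]:
                assert pt.rf_distance(a, b) > 0  # all topologies distinct


def test_nni_context_quartet():
    t = pt.parse_newick("((a,b),(c,d));")
    (edge,) = [s for s in pt.splits_of(t).nontrivial]
    a, b, c, d = pt.resolve_nni_context(t, edge)
    taxa = t.taxa
    assert {a, b} == {taxa.mask_of("a"), taxa.mask_of("b")}
    assert {c, d} == {taxa.mask_of("c"), taxa.mask_of("d")}


def test_nni_context_matches_flood_fill(rng):
    """Oracle: the four context sets are the side masks of the four
    incident edges."""
    for _ in range(10):
        t = random_tree(rng, 6, 16)
        for u, v in t.interior_edges():
            edge = t.split_for_edge(u, v)
            a, b, c, d = pt.resolve_nni_context(t, edge)
            incident = {
                t.side_mask(u, w) for w in t._adj[u] if w != v
            } | {
                t.side_mask(v, w) for w in t._adj[v] if w != u
            }
            assert {a, b, c, d} == incident
            assert a | b | c | d == t.leaf_mask
            assert a & b == a & c == a & d == b & c == b & d == c & d == 0


def test_nni_quartet_exhaustive():
    t = pt.parse_newick("((a,b),(c,d));")
    results = {pt.write_newick(pt.apply_nni(t, m)) for m in pt.enumerate_nni_moves(t)}
    expected = {
        pt.write_newick(pt.parse_newick(nw, taxa=t.taxa))
        for nw in ("((a,c),(b,d));", "((a,d),(b,c));")
    }
    assert results == expected


def test_nni_predicted_symmetric_difference(rng):
    for _ in range(8):
        t = random_tree(rng)
        for m in pt.enumerate_nni_moves(t):
            tn = pt.apply_nni(t, m)
            got = pt.splits_of(t).symmetric_difference(pt.splits_of(tn))
            assert got == predicted_split_changes(m, t.leaf_mask)


def test_nni_involution(rng):
    for _ in range(6):
        t = random_tree(rng)
        m = pt.enumerate_nni_moves(t)[0]
        tn = pt.apply_nni(t, m)
        # the same exchange on the new tree restores the original topology
        back = [
            mv for mv in pt.enumerate_nni_moves(tn)
            if pt.rf_distance(t, pt.apply_nni(tn, mv)) == 0
        ]
        assert back


def test_apply_does_not_mutate_input(rng):
    t = random_tree(rng)
    before = pt.write_newick(t)
    for m in pt.enumerate_nni_moves(t):
        pt.apply_nni(t, m)
    mv = random_spr(t, rng)
    if mv:
        pt.apply_spr(t, mv)
    mv = random_tbr(t, rng)
    if mv:
        pt.apply_tbr(t, mv)
    assert pt.write_newick(t) == before


def test_stale_nni_move_rejected(rng):
    t1 = random_tree(rng, 10, 10)
    t2 = yule_harding_tree(10, rng, taxa=t1.taxa)
    for m in pt.enumerate_nni_moves(t1):
        try:
            tn = pt.apply_nni(t2, m)
        except StaleMoveError:
            continue
        # if the edge also exists in t2 the context masks must have matched
        assert pt.rf_distance(t2, tn) == 2
        break


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------


def caterpillar(labels):
    inner = labels[-1]
    for lab in reversed(labels[:-1]):
        inner = f"({lab},{inner})"
    return pt.parse_newick(inner + ";")


def test_spr_path_decomposition_caterpillar():
    t = caterpillar(["a", "b1", "b2", "b3", "b4"])
    taxa = t.taxa
    prune = Split(taxa.mask_of(["a"]), t.leaf_mask)
    regraft = Split(taxa.mask_of(["b4"]), t.leaf_mask)
    mv = pt.build_spr_move(t, prune, regraft)
    assert mv.a == taxa.mask_of(["a"])
    assert mv.path == tuple(taxa.mask_of([f"b{i}"]) for i in range(1, 5))
    assert mv.n == 4 and not mv.is_nni_equivalent


def test_spr_nni_equivalent_case(rng):
    """n = 3 SPR produces a tree one NNI away (RF 2) and is flagged."""
    t = caterpillar(["a", "b1", "b2", "b3"])
    taxa = t.taxa
    mv = pt.build_spr_move(
        t,
        Split(taxa.mask_of(["a"]), t.leaf_mask),
        Split(taxa.mask_of(["b3"]), t.leaf_mask),
    )
    assert mv.n == 3 and mv.is_nni_equivalent
    tn = pt.apply_spr(t, mv)
    assert pt.rf_distance(t, tn) == 2
    nni_results = {
        pt.write_newick(pt.apply_nni(t, m)) for m in pt.enumerate_nni_moves(t)
    }
    assert pt.write_newick(tn) in nni_results


def test_spr_identity_placements_rejected():
    t = caterpillar(["a", "b1", "b2", "b3", "b4"])
    taxa = t.taxa
    prune = Split(taxa.mask_of(["a"]), t.leaf_mask)
    with pytest.raises(InvalidMoveError):
        pt.build_spr_move(t, prune, prune)
    # regraft adjacent to the attachment node: n would be 2
    with pytest.raises(InvalidMoveError):
        pt.build_spr_move(t, prune, Split(taxa.mask_of(["b1"]), t.leaf_mask))


def test_spr_rf_formula_caterpillar():
    # 8-taxon caterpillar, pruning the head across the tree: n = 5 -> RF 6
    t = caterpillar(["a", "b1", "b2", "b3", "b4", "b5", "b6", "b7"])
    taxa = t.taxa
    mv = pt.build_spr_move(
        t,
        Split(taxa.mask_of(["a"]), t.leaf_mask),
        Split(taxa.mask_of(["b4"]), t.leaf_mask),
    )
    assert mv.n == 5
    assert pt.rf_distance(t, pt.apply_spr(t, mv)) == 6


def test_spr_reversibility(rng):
    for _ in range(10):
        t = random_tree(rng)
        mv = random_spr(t, rng)
        if mv is None:
            continue
        t2 = pt.apply_spr(t, mv)
        # prune the same subtree back onto an edge of the original position
        back = None
        for s in pt.splits_of(t2):
            try:
                cand = pt.build_spr_move(t2, mv.prune_edge, s)
            except InvalidMoveError:
                continue
            if pt.rf_distance(t, pt.apply_spr(t2, cand)) == 0:
                back = cand
                break
        assert back is not None


# ---------------------------------------------------------------------------
# TBR
# ---------------------------------------------------------------------------


def two_sided_tree():
    # B side: cherries B1..B4 along a path; C side: cherries C1..C4
    def side(prefix):
        parts = [f"({prefix}{i}a,{prefix}{i}b)" for i in range(1, 5)]
        return f"({parts[0]},({parts[1]},({parts[2]},{parts[3]})))"
    return pt.parse_newick(f"({side('b')},{side('c')});")


def tbr_on_two_sided(t, b_idx=4, c_idx=4):
    taxa = t.taxa
    b_labels = [f"b{i}{x}" for i in range(1, 5) for x in "ab"]
    e = Split(taxa.mask_of(b_labels), t.leaf_mask)
    rb = Split(taxa.mask_of([f"b{b_idx}a", f"b{b_idx}b"]), t.leaf_mask)
    rc = Split(taxa.mask_of([f"c{c_idx}a", f"c{c_idx}b"]), t.leaf_mask)
    return pt.build_tbr_move(t, e, rb, rc)


def test_tbr_path_decomposition():
    t = two_sided_tree()
    mv = tbr_on_two_sided(t)
    taxa = t.taxa
    assert mv.n == 4 and mv.m == 4
    assert mv.b_path == tuple(
        taxa.mask_of([f"b{i}a", f"b{i}b"]) for i in range(1, 5)
    )
    assert mv.c_path == tuple(
        taxa.mask_of([f"c{i}a", f"c{i}b"]) for i in range(1, 5)
    )


def test_tbr_rf_formula_and_preserved_bisection():
    t = two_sided_tree()
    mv = tbr_on_two_sided(t)
    tn = pt.apply_tbr(t, mv)
    assert pt.rf_distance(t, tn) == 2 * (4 + 4 - 4)
    assert mv.bisect_edge in pt.splits_of(tn)
    assert mv.bisect_edge in pt.splits_of(t)


def test_tbr_identity_rejected():
    t = two_sided_tree()
    with pytest.raises(InvalidMoveError):
        tbr_on_two_sided(t, b_idx=1, c_idx=1)  # n = m = 2


def test_tbr_nni_and_spr_equivalent_flags():
    t = two_sided_tree()
    assert tbr_on_two_sided(t, b_idx=2, c_idx=1).is_nni_equivalent
    mv = tbr_on_two_sided(t, b_idx=3, c_idx=1)
    assert mv.is_spr_equivalent and not mv.is_nni_equivalent


def test_tbr_m2_equals_spr():
    """A TBR with one trivial side reproduces the corresponding SPR."""
    t = two_sided_tree()
    mv = tbr_on_two_sided(t, b_idx=4, c_idx=1)  # m = 2
    tn = pt.apply_tbr(t, mv)
    taxa = t.taxa
    c_labels = [f"c{i}{x}" for i in range(1, 5) for x in "ab"]
    spr = pt.build_spr_move(
        t,
        Split(taxa.mask_of(c_labels), t.leaf_mask),
        Split(taxa.mask_of(["b4a", "b4b"]), t.leaf_mask),
    )
    assert pt.rf_distance(tn, pt.apply_spr(t, spr)) == 0


def test_tbr_reconnects_must_be_in_different_components():
    t = two_sided_tree()
    taxa = t.taxa
    b_labels = [f"b{i}{x}" for i in range(1, 5) for x in "ab"]
    e = Split(taxa.mask_of(b_labels), t.leaf_mask)
    rb = Split(taxa.mask_of(["b3a", "b3b"]), t.leaf_mask)
    rb2 = Split(taxa.mask_of(["b4a", "b4b"]), t.leaf_mask)
    with pytest.raises(InvalidMoveError):
        pt.build_tbr_move(t, e, rb, rb2)


# ---------------------------------------------------------------------------
# predicted RF on random moves (all kinds)
# ---------------------------------------------------------------------------


def test_predicted_rf_random_moves(rng):
    """predicted_rf equals the computed RF on 200+ random moves, 6-30 taxa."""
    checked = 0
    while checked < 200:
        t = random_tree(rng, 6, 30)
        for sampler in (random_spr, random_tbr):
            mv = sampler(t, rng)
            if mv is None:
                continue
            tn = pt.apply_move(t, mv)
            assert pt.rf_distance(t, tn) == pt.predicted_rf(mv)
            got = pt.splits_of(t).symmetric_difference(pt.splits_of(tn))
            assert got == predicted_split_changes(mv, t.leaf_mask)
            checked += 1
        for mv in pt.enumerate_nni_moves(t)[:2]:
            assert pt.rf_distance(t, pt.apply_nni(t, mv)) == pt.predicted_rf(mv) == 2
            checked += 1


def test_enumerators_respect_radius(rng):
    t = random_tree(rng, 10, 14)
    for mv in enumerate_spr_moves(t, radius=3):
        assert 3 <= mv.n <= 4
    count = 0
    for mv in enumerate_tbr_moves(t, radius=2):
        assert mv.n <= 3 and mv.m <= 3
        count += 1
        if count > 200:
            break
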
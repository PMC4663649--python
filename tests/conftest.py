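"""Shared helpers: seeded RNG, random trees, random move samplers."""

from __future__ import annotations

import numpy as np
import pytest

import pterrace as pt
from pterrace.rearrange import InvalidMoveError
from pterrace.simulate import yule_harding_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_tree(rng, n_min=6, n_max=25):
    n = int(rng.integers(n_min, n_max + 1))
    return yule_harding_tree(n, rng)


def random_nni(tree, rng):
    moves = pt.enumerate_nni_moves(tree)
    if not moves:
        return None
    return moves[int(rng.integers(len(moves)))]


def random_spr(tree, rng, tries=12):
    splits = list(pt.splits_of(tree))
    for _ in range(tries):
        i, j = rng.choice(len(splits), 2, replace=False)
        try:
            return pt.build_spr_move(tree, splits[int(i)], splits[int(j)])
        except InvalidMoveError:
            continue
    return None


def random_tbr(tree, rng, tries=20):
    splits = list(pt.splits_of(tree))
    for _ in range(tries):
        i, j, k = rng.choice(len(splits), 3, replace=False)
        try:
            return pt.build_tbr_move(
                tree, splits[int(i)], splits[int(j)], splits[int(k)]
            )
        except InvalidMoveError:
            continue
    return None


def random_subset_mask(tree, rng, size=None):
    n = len(tree.taxa)
    if size is None:
        size = int(rng.integers(1, n + 1))
    picks = rng.choice(n, size=size, replace=False)
    return int(sum(1 << int(i) for i in picks))
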
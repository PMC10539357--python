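"""Shared fixtures: canonical small trees and an independent event-by-event
birth-death simulator used as an oracle for the tree generator."""

from __future__ import annotations

import numpy as np
import pytest

from basinrates.treeio import Phylogeny, parse_newick


@pytest.fixture
def two_tip_tree() -> Phylogeny:
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def balanced_four_tree() -> Phylogeny:
    """Balanced ultrametric 4-tip tree, all branch lengths 1, depth 2."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def star_tree() -> Phylogeny:
    return parse_newick("(A:2,B:2,C:2,D:2,E:2);")


def gillespie_one(rng: np.random.Generator, lam: float, mu: float, T: float) -> int:
    """Brute-force event-by-event birth-death from one lineage.

    Global clock: with k lineages the next event is Exp(k*(lam+mu)); the
    event is a birth w.p. lam/(lam+mu).  Returns the extant count at T
    (0 on extinction).
    """
    k = 1
    t = 0.0
    total = lam + mu
    while k > 0:
        t += rng.exponential(1.0 / (k * total))
        if t >= T:
            return k
        if rng.random() < lam / total:
            k += 1
        else:
            k -= 1
    return 0


def gillespie_crown_surviving(
    rng: np.random.Generator, lam: float, mu: float, T: float
) -> int:
    """Crown tip count conditioned on both crown lineages surviving.

    The two crown lineages are independent, so each side is drawn from the
    single-lineage simulator by rejection on survival.
    """
    sides = []
    while len(sides) < 2:
        n = gillespie_one(rng, lam, mu, T)
        if n >= 1:
            sides.append(n)
    return sides[0] + sides[1]
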
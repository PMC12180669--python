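"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from coph import annotate, as_descending, random_tree, split
from coph.naive import restricted_power_sum

KINDS = ("depth", "height", "size")


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


def random_pair(rng, n, model=None, kind="depth"):
    """One random annotated tree pair over a shared label set."""
    model = model or ("yule" if rng.integers(2) else "uniform")
    t1 = random_tree(model, n, rng)
    t2 = random_tree(model, n, rng)
    return annotate(t1, kind), annotate(t2, kind)


def category_pairs(sp1, sp2):
    """The ten Table-style categories of unordered leaf pairs induced by two
    median splits: four non-mixed (N1-N4, diagonal pairs included), four
    single-mixed (S1-S4) and two double-mixed (D1, D2)."""
    cAA = sp1.A & sp2.A
    cAB = sp1.A & sp2.B
    cBA = sp1.B & sp2.A
    cBB = sp1.B & sp2.B

    def within(cell):
        cell = sorted(cell)
        return {
            (cell[i], cell[j]) for i in range(len(cell)) for j in range(i, len(cell))
        }

    def across(c1, c2):
        return {tuple(sorted((a, b))) for a in c1 for b in c2}

    return {
        "N1": within(cAA),
        "N2": within(cAB),
        "N3": within(cBA),
        "N4": within(cBB),
        "S1": across(cAA, cBA),  # AB|A'A'
        "S2": across(cAB, cBB),  # AB|B'B'
        "S3": across(cAA, cAB),  # AA|A'B'
        "S4": across(cBA, cBB),  # BB|A'B'
        "D1": across(cAA, cBB),  # AB|A'B'
        "D2": across(cAB, cBA),  # AB|B'A'
    }


def oracle_restricted(at1, at2, p, pairs):
    """Naive power sum (max for p = inf) over an explicit pair set, on the
    jointly descending-normalized annotations."""
    return restricted_power_sum(as_descending(at1), as_descending(at2), p, pairs)
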
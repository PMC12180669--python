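"""The divide-and-conquer path: SeqPrd, counter sequences, the ten partial
distances against restricted oracles, and full oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coph import (
    INF,
    annotate,
    as_descending,
    coph_distance,
    coph_distance_inf,
    get_cntr,
    median_vertex,
    naive_distance,
    parse_newick,
    partial_double_mixed_aligned,
    partial_double_mixed_crossed,
    partial_single_mixed,
    random_tree,
    seq_prd,
    split,
)
from coph.fastdist import SINGLE_MIXED_VARIANTS, binomials

from conftest import KINDS, category_pairs, oracle_restricted


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


def test_binomials_match_factorial_ratios():
    for p in (1, 2, 7, 31, 200):
        assert binomials(p) == [math.comb(p, i) for i in range(p + 1)]


@given(
    p=st.integers(1, 7),
    alpha=st.lists(st.integers(-30, 30), max_size=20),
    beta=st.lists(st.integers(-30, 30), max_size=20),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_seq_prd_equals_nested_loop(p, alpha, beta):
    alpha, beta = sorted(alpha), sorted(beta)
    expected = sum(abs(a - b) ** p for a in alpha for b in beta)
    assert seq_prd(p, alpha, beta) == expected


def test_seq_prd_edge_cases():
    assert seq_prd(1, [1], [1]) == 0
    assert seq_prd(1, [0, 2], [1]) == 2
    assert seq_prd(2, [1, 3], [2, 4]) == 12
    assert seq_prd(3, [], [1, 2]) == 0


def test_get_cntr_examples():
    t = parse_newick("((a,b),c);")
    at = annotate(t, "depth")
    m = t.parent[t.leaf_of_label("a")]
    sp = split(t, m)
    assert get_cntr(at, sp, {"c"}) == [0]
    assert get_cntr(at, sp, set()) == []

    cat = parse_newick("(((a,b),c),d);")
    atc = annotate(cat, "depth")
    mc = cat.parent[cat.leaf_of_label("a")]
    spc = split(cat, mc)
    assert get_cntr(atc, spc, {"c", "d"}) == [0, 1]


def test_get_cntr_sorted_on_random_splits(rng):
    for _ in range(50):
        n = int(rng.integers(2, 64))
        t = random_tree("yule", n, rng)
        at = as_descending(annotate(t, "size"))
        sp = split(t, median_vertex(t))
        seq = get_cntr(at, sp, sp.A)
        assert seq == sorted(seq)
        assert len(seq) == len(sp.A)


# ---------------------------------------------------------------------------
# the ten partial distances vs their restricted oracles
# ---------------------------------------------------------------------------

_CAT_OF_VARIANT = {
    "AA|A'B'": "S3",
    "BB|A'B'": "S4",
    "AB|A'A'": "S1",
    "AB|B'B'": "S2",
}


def _random_split_pair(rng, n, kind):
    model1 = "yule" if rng.integers(2) else "uniform"
    t1 = random_tree(model1, n, rng)
    t2 = random_tree("uniform", n, rng)
    a1 = as_descending(annotate(t1, kind))
    a2 = as_descending(annotate(t2, kind))
    sp1 = split(t1, median_vertex(t1))
    sp2 = split(t2, median_vertex(t2))
    return a1, a2, sp1, sp2


@pytest.mark.parametrize("p", [1, 2, 3, 4, 5])
def test_double_mixed_aligned_matches_restricted_oracle(p, rng):
    for _ in range(12):
        n = int(rng.integers(2, 33))
        a1, a2, sp1, sp2 = _random_split_pair(rng, n, KINDS[int(rng.integers(3))])
        cats = category_pairs(sp1, sp2)
        got = partial_double_mixed_aligned(a1, a2, sp1, sp2, p)
        assert got == oracle_restricted(a1, a2, p, cats["D1"])


@pytest.mark.parametrize("p", [1, 2, 3, 4, 5])
def test_double_mixed_crossed_matches_restricted_oracle(p, rng):
    for _ in range(12):
        n = int(rng.integers(2, 33))
        a1, a2, sp1, sp2 = _random_split_pair(rng, n, KINDS[int(rng.integers(3))])
        cats = category_pairs(sp1, sp2)
        got = partial_double_mixed_crossed(a1, a2, sp1, sp2, p)
        assert got == oracle_restricted(a1, a2, p, cats["D2"])


@pytest.mark.parametrize("variant", SINGLE_MIXED_VARIANTS)
@pytest.mark.parametrize("p", [1, 2, 3, 4, 5])
def test_single_mixed_matches_restricted_oracle(variant, p, rng):
    """The primary correctness surface of the odd/even sweep machinery: each
    variant must reproduce the naive double loop on its own pair set."""
    for _ in range(12):
        n = int(rng.integers(2, 33))
        a1, a2, sp1, sp2 = _random_split_pair(rng, n, KINDS[int(rng.integers(3))])
        cats = category_pairs(sp1, sp2)
        got = partial_single_mixed(a1, a2, sp1, sp2, p, variant)
        assert got == oracle_restricted(a1, a2, p, cats[_CAT_OF_VARIANT[variant]])


def test_single_mixed_empty_pair_set_is_zero():
    # a 2-leaf pair: A = one leaf, B = the other; AA pairs cannot exist
    t1 = parse_newick("(a,b);")
    t2 = parse_newick("(a,b);")
    a1 = annotate(t1, "depth")
    a2 = annotate(t2, "depth")
    sp1, sp2 = split(t1, median_vertex(t1)), split(t2, median_vertex(t2))
    assert partial_single_mixed(a1, a2, sp1, sp2, 3, "AA|A'B'") == 0


def test_partial_sums_cover_everything(rng):
    """Summing the ten partial distances (non-mixed ones through the
    restricted oracle) reproduces the full naive power sum — independently of
    the recursion."""
    for _ in range(10):
        n = int(rng.integers(4, 33))
        kind = KINDS[int(rng.integers(3))]
        a1, a2, sp1, sp2 = _random_split_pair(rng, n, kind)
        cats = category_pairs(sp1, sp2)
        for p in (1, 2, 3):
            total = sum(
                oracle_restricted(a1, a2, p, cats[f"N{i}"]) for i in (1, 2, 3, 4)
            )
            total += partial_double_mixed_aligned(a1, a2, sp1, sp2, p)
            total += partial_double_mixed_crossed(a1, a2, sp1, sp2, p)
            for variant in SINGLE_MIXED_VARIANTS:
                total += partial_single_mixed(a1, a2, sp1, sp2, p, variant)
            assert total == naive_distance(a1, a2, p).power_sum


# ---------------------------------------------------------------------------
# full distances
# ---------------------------------------------------------------------------


def test_worked_example():
    a1 = annotate(parse_newick("((a,b),c);"), "depth")
    a2 = annotate(parse_newick("(a,(b,c));"), "depth")
    assert coph_distance(a1, a2, 1).power_sum == 4
    assert coph_distance_inf(a1, a2).power_sum == 1
    assert coph_distance(a1, a1, 7).power_sum == 0
    assert coph_distance_inf(a1, a1).distance == 0.0


@pytest.mark.parametrize("kind", KINDS)
def test_oracle_equivalence_sampled(kind, rng):
    """Fast power sums match the quadratic oracle bit-exactly across sizes,
    models and norms (the full-scale sweep lives in the acceptance tests)."""
    ps = [1, 2, 3, 4, 5, 7, 10, 13, 50, INF]
    for i in range(60):
        n = int(rng.integers(2, 129))
        model = "yule" if i % 2 else "uniform"
        t1, t2 = random_tree(model, n, rng), random_tree(model, n, rng)
        a1, a2 = annotate(t1, kind), annotate(t2, kind)
        p = ps[i % len(ps)]
        fast = coph_distance_inf(a1, a2) if p == INF else coph_distance(a1, a2, p)
        assert fast.power_sum == naive_distance(a1, a2, p).power_sum


def test_base_threshold_irrelevant_to_result(rng):
    for _ in range(10):
        n = int(rng.integers(6, 64))
        t1, t2 = random_tree("yule", n, rng), random_tree("uniform", n, rng)
        a1, a2 = annotate(t1, "height"), annotate(t2, "height")
        ref = coph_distance(a1, a2, 3).power_sum
        for thr in (5, 12, 100):
            assert coph_distance(a1, a2, 3, base_threshold=thr).power_sum == ref


def test_weighted_contributions_close_to_oracle(rng):
    for _ in range(15):
        n = int(rng.integers(2, 48))
        t1, t2 = random_tree("yule", n, rng), random_tree("yule", n, rng)
        for t in (t1, t2):
            t.edge_weight = [float(x) for x in rng.uniform(0.05, 2.0, t.n_vertices)]
        a1 = annotate(t1, "weighted_depth")
        a2 = annotate(t2, "weighted_depth")
        for p in (1, 2, 5, 10):
            fast = coph_distance(a1, a2, p).power_sum
            ref = naive_distance(a1, a2, p).power_sum
            assert fast == pytest.approx(ref, rel=1e-9)
        dinf = coph_distance_inf(a1, a2).distance
        assert dinf == pytest.approx(naive_distance(a1, a2, INF).distance, rel=1e-12)


def test_weighted_p_cap_enforced(rng):
    t1, t2 = random_tree("yule", 8, rng), random_tree("yule", 8, rng)
    for t in (t1, t2):
        t.edge_weight = [float(x) for x in rng.uniform(0.5, 1.5, t.n_vertices)]
    a1, a2 = annotate(t1, "weighted_depth"), annotate(t2, "weighted_depth")
    with pytest.raises(ValueError, match="cap"):
        coph_distance(a1, a2, 50)
    assert coph_distance(a1, a2, 50, float_p_cap=50).power_sum >= 0


def test_cherry_root_separation_gives_n_minus_2():
    """Two leaves forming a cherry in one 100-leaf tree but straddling the
    root in the other: subtree sizes 2 vs 100, L-infinity distance 98."""
    labels = [f"L{i:03d}" for i in range(100)]
    x, y, rest = labels[0], labels[1], labels[2:]
    s = f"({x},{y})"
    for z in rest:
        s = f"({s},{z})"
    t1 = parse_newick(s + ";")
    s2 = rest[0]
    for z in rest[1:]:
        s2 = f"({s2},{z})"
    t2 = parse_newick(f"({x},({y},{s2}));")
    a1, a2 = annotate(t1, "size"), annotate(t2, "size")
    assert coph_distance_inf(a1, a2).power_sum == 98
    assert naive_distance(a1, a2, INF).power_sum == 98


def test_rejections():
    a1 = annotate(parse_newick("((a,b),c);"), "depth")
    a2 = annotate(parse_newick("(a,(b,d));"), "depth")
    with pytest.raises(ValueError, match="leaf sets"):
        coph_distance(a1, a2, 2)
    a3 = annotate(parse_newick("(a,(b,c));"), "size")
    with pytest.raises(ValueError, match="direction"):
        coph_distance(a1, a3, 2)
    with pytest.raises(ValueError):
        coph_distance(a1, a1, 0)
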
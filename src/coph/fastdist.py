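"""Near-linear divide-and-conquer computation of L_p cophenetic distances.

The trees are split at median vertices into upper (A) and lower (B) leaf
sets; the n(n+1)/2 leaf pairs (diagonal included) fall into ten categories by
their placement relative to the two splits:

* four non-mixed categories (both leaves in the same part of both trees) —
  handled by contracting both trees to the shared leaf set and recursing;
* two double-mixed categories — pairs straddling the median in both trees,
  whose lcas lie on both median paths; one reduces to a closed form over the
  aligned pairs, the other to a sorted-sequence power-sum product (SeqPrd);
* four single-mixed categories — pairs straddling the median in exactly one
  tree; computed by a bottom-up sweep of that tree's upper or lower part with
  per-vertex power-sum accumulators (separate odd-p and even-p machinery,
  since |a-b|^p = (a-b)^p only for even p).

All power sums, binomials and alternating-sign expansions run in exact
arbitrary-precision integer arithmetic whenever both contributions are
integer-valued: at p = 100 the binomial expansions suffer catastrophic
cancellation and overflow in 64-bit floats, and exactness makes agreement
with the quadratic oracle bit-exact.  For real-valued (weighted)
contributions the supported p is capped (default 15).

The L-infinity norm is a separate code path: the same p = 1 sweep shapes with
every sum replaced by a maximum.
"""

from __future__ import annotations

import math
from bisect import bisect_left

from .contributions import AnnotatedTree, as_descending, check_pair
from .naive import INF, DistanceResult, naive_distance
from .partition import MedianSplit, contract, median_vertex, split
from .treeio import NO_VERTEX, LabeledTree

__all__ = [
    "PowerVector",
    "binomials",
    "get_cntr",
    "seq_prd",
    "partial_double_mixed_aligned",
    "partial_double_mixed_crossed",
    "partial_single_mixed",
    "coph_distance",
    "coph_distance_inf",
    "SINGLE_MIXED_VARIANTS",
]

BASE_THRESHOLD = 5  # recursion bottoms out in the quadratic oracle
FLOAT_P_CAP = 15  # largest p admitted for non-integer contributions

SINGLE_MIXED_VARIANTS = ("AA|A'B'", "BB|A'B'", "AB|A'A'", "AB|B'B'")


def binomials(p: int) -> list[int]:
    """C(p, i) for i = 0..p via the multiplicative recurrence, exactly."""
    a = [1] * (p + 1)
    for i in range(1, p + 1):
        a[i] = a[i - 1] * (p - i + 1) // i
    return a


class PowerVector:
    """Length-(p+1) sequence of power sums: entry l holds sum x^l over the
    accumulated terms, so entry 0 is the term count."""

    __slots__ = ("values",)

    def __init__(self, values):
        self.values = list(values)

    @classmethod
    def zero(cls, p: int) -> "PowerVector":
        return cls([0] * (p + 1))

    @classmethod
    def powers(cls, x, p: int) -> "PowerVector":
        vals = [1] * (p + 1)
        for l in range(1, p + 1):
            vals[l] = vals[l - 1] * x
        return cls(vals)

    def __add__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector([a + b for a, b in zip(self.values, other.values)])

    def __sub__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector([a - b for a, b in zip(self.values, other.values)])

    def __eq__(self, other) -> bool:
        return isinstance(other, PowerVector) and self.values == other.values

    def __repr__(self) -> str:  # pragma: no cover
        return f"PowerVector({self.values})"


# None stands for the zero vector in the accumulators (most leaves carry
# nothing, and skipping the allocation matters on big trees)
def _acc_add(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def _acc_sub(a, b, p):
    if b is None:
        return a
    if a is None:
        return PowerVector.zero(p) - b
    return a - b


# ---------------------------------------------------------------------------
# Double-mixed machinery
# ---------------------------------------------------------------------------


def get_cntr(at: AnnotatedTree, sp: MedianSplit, X) -> list:
    """Counter sequence: for each leaf x in X (a subset of the split's upper
    set A) the contribution xi(lca(x, t)).  Emitted by walking the median
    path root -> t, so with descending xi the sequence is non-decreasing and
    needs no sort."""
    counts = [0] * len(sp.median_path)
    for lab in X:
        counts[sp.path_index[lab]] += 1
    gamma = []
    for i, m in enumerate(sp.median_path):
        if counts[i]:
            gamma.extend([at.xi[m]] * counts[i])
    return gamma


def seq_prd(p: int, alpha, beta, binoms=None):
    """Sum of |alpha_i - beta_j|^p over all cross pairs of two sorted
    (non-decreasing) sequences, in O(p(k+m)) time via prefix power sums and
    a binomial expansion.  Exact for integer input."""
    alpha, beta = list(alpha), list(beta)
    if not alpha or not beta:
        return 0
    if alpha[-1] > beta[-1]:
        alpha, beta = beta, alpha
    if binoms is None:
        binoms = binomials(p)
    k, m = len(alpha), len(beta)

    # prefix power sums of alpha at each beta cut point
    run = [0] * (p + 1)
    prefix = []  # prefix[j][l] = sum of alpha_i^l over alpha_i <= beta_j
    i = 0
    for j in range(m):
        while i < k and alpha[i] <= beta[j]:
            x = alpha[i]
            xl = 1
            for l in range(p + 1):
                run[l] += xl
                xl *= x
            i += 1
        prefix.append(run.copy())
    total_pow = prefix[-1]  # alpha[-1] <= beta[-1] so every alpha is consumed

    total = 0
    for j in range(m):
        bj = beta[j]
        bpow = PowerVector.powers(bj, p).values
        sj = prefix[j]
        acc = 0
        for l in range(p + 1):
            term = bpow[l] * sj[p - l] + bpow[p - l] * (total_pow[l] - sj[l])
            acc += binoms[l] * term if (p - l) % 2 == 0 else -binoms[l] * term
        total += acc
    return total


def _seq_max(alpha, beta):
    """max |alpha_i - beta_j| over cross pairs of sorted sequences."""
    if not alpha or not beta:
        return None
    return max(alpha[-1] - beta[0], beta[-1] - alpha[0])


def _beta_of(at_other: AnnotatedTree, sp_other: MedianSplit, lab: str):
    """x.beta: the other tree's contribution at lca(x, t') — a median-path
    vertex looked up through the split's hang map."""
    return at_other.xi[sp_other.median_path[sp_other.path_index[lab]]]


def partial_double_mixed_aligned(
    at1: AnnotatedTree, at2: AnnotatedTree, sp1: MedianSplit, sp2: MedianSplit, p: int
):
    """Partial distance for pairs upper in both trees x lower in both trees
    (category D1): each such pair's lca sits on the median path of both
    trees and depends only on x, so the sum collapses to a single sweep over
    A and A' scaled by |B and B'|."""
    bb = len(sp1.B & sp2.B)
    if bb == 0:
        return 0
    s = 0
    for lab in sp1.A & sp2.A:
        d = _beta_of(at1, sp1, lab) - _beta_of(at2, sp2, lab)
        s += abs(d) ** p
    return s * bb


def partial_double_mixed_crossed(
    at1: AnnotatedTree, at2: AnnotatedTree, sp1: MedianSplit, sp2: MedianSplit, p: int
):
    """Partial distance for pairs upper in one tree but lower in the other
    (category D2), via SeqPrd on the two median-path counter sequences."""
    alpha = get_cntr(at1, sp1, sp1.A & sp2.B)
    beta = get_cntr(at2, sp2, sp1.B & sp2.A)
    return seq_prd(p, alpha, beta)


# ---------------------------------------------------------------------------
# Single-mixed machinery (Algorithms 3 and 4 plus the variant adaptations)
# ---------------------------------------------------------------------------


def _region_orders(tree: LabeledTree, region: str, t: int):
    """(postorder, region_root, placeholder) for the upper or lower part of a
    median split.  In the upper region the median vertex t acts as a leaf
    (the placeholder replacing the lower tree)."""
    if region == "upper":
        root, placeholder = tree.root, t
    else:
        root, placeholder = t, None
    post = []
    stack = [root]
    while stack:
        v = stack.pop()
        post.append(v)
        if not tree.is_leaf(v) and v != placeholder:
            stack.append(tree.left[v])
            stack.append(tree.right[v])
    post.reverse()
    return post, root, placeholder


def _single_mixed_region(
    at: AnnotatedTree,
    region: str,
    t: int,
    beta: dict[str, object],
    y_labels: set[str],
    p,
    binoms,
):
    """One single-mixed partial distance: traverse the given region of
    ``at``'s tree; leaves with labels in ``beta`` contribute power vectors of
    their beta value, pairs are counted against ``y_labels`` leaves under each
    vertex's sibling.  ``p`` is a positive integer, or INF for the max-monoid
    sweep used by the L-infinity norm."""
    tree, xi = at.tree, at.xi
    post, region_root, placeholder = _region_orders(tree, region, t)
    if len(post) == 1:  # degenerate region: no pairs
        return None if p == INF else 0

    def is_region_leaf(v: int) -> bool:
        return tree.is_leaf(v) or v == placeholder

    ycount: dict[int, int] = {}
    for v in post:
        if is_region_leaf(v):
            ycount[v] = 1 if (tree.label[v] in y_labels) else 0
        else:
            ycount[v] = ycount[tree.left[v]] + ycount[tree.right[v]]

    if p == INF:
        return _single_mixed_max(tree, xi, post, region_root, is_region_leaf, beta, ycount)
    if p % 2 == 0:
        return _single_mixed_even(tree, xi, post, region_root, is_region_leaf, beta, ycount, p, binoms)
    return _single_mixed_odd(
        tree, xi, post, region_root, placeholder, is_region_leaf, beta, ycount, p, binoms
    )


def _single_mixed_even(tree, xi, post, region_root, is_region_leaf, beta, ycount, p, binoms):
    # sum (x.beta - xi(parent))^p needs no sign analysis when p is even:
    # one bottom-up pass of plain power-sum vectors
    sigma: dict[int, PowerVector | None] = {}
    total = 0
    ppow_cache: dict[object, list] = {}
    for v in post:
        if is_region_leaf(v):
            lab = tree.label[v]
            sigma[v] = (
                PowerVector.powers(beta[lab], p) if lab in beta else None
            )
        else:
            sigma[v] = _acc_add(sigma.pop(tree.left[v]), sigma.pop(tree.right[v]))
        if v == region_root:
            continue
        sv = sigma[v]
        par = tree.parent[v]
        yv = ycount[tree.right[par] if tree.left[par] == v else tree.left[par]]
        if yv == 0 or sv is None:
            continue
        xp = xi[par]
        if xp not in ppow_cache:
            ppow_cache[xp] = PowerVector.powers(xp, p).values
        xpow = ppow_cache[xp]
        vals = sv.values
        acc = 0
        for l in range(p + 1):
            term = binoms[l] * xpow[p - l] * vals[l]
            acc += term if (p - l) % 2 == 0 else -term
        total += yv * acc
    return total


def _single_mixed_odd(
    tree, xi, post, region_root, placeholder, is_region_leaf, beta, ycount, p, binoms
):
    # odd p: |a - b|^p flips sign with a - b, so leaves are partitioned by
    # whether x.beta has been overtaken by xi along the path; the handover
    # points (omega) are found by binary search on the sorted root-to-leaf
    # contribution array maintained during a DFS, and transferred between the
    # sigma+ / sigma- accumulators through per-vertex delta vectors
    delta: dict[int, PowerVector] = {}
    sigma_p: dict[int, PowerVector | None] = {}
    sigma_m: dict[int, PowerVector | None] = {}

    # preprocessing DFS with the path stack
    path_v: list[int] = []
    path_xi: list = []
    stack: list[tuple[int, int]] = [(region_root, 0)]
    while stack:
        v, stage = stack.pop()
        if stage == 1:
            path_v.pop()
            path_xi.pop()
            continue
        path_v.append(v)
        path_xi.append(xi[v])
        stack.append((v, 1))
        if not is_region_leaf(v):
            stack.append((tree.right[v], 0))
            stack.append((tree.left[v], 0))
            continue
        lab = tree.label[v]
        if lab not in beta:
            sigma_p[v] = sigma_m[v] = None
            continue
        b = beta[lab]
        bstar = PowerVector.powers(b, p)
        if b <= xi[v]:
            # omega_x: the ancestor closest to the root with xi >= x.beta;
            # path_xi is non-decreasing root -> leaf, so bisect finds it
            w = path_v[bisect_left(path_xi, b)]
            if w in delta:
                delta[w] = delta[w] + bstar
            else:
                delta[w] = bstar
        if v != region_root and b <= xi[tree.parent[v]]:
            sigma_p[v], sigma_m[v] = bstar, None
        else:
            sigma_p[v], sigma_m[v] = None, bstar

    total = 0
    ppow_cache: dict[object, list] = {}
    for v in post:
        if not is_region_leaf(v):
            dv = delta.get(v)
            sp_ = _acc_add(sigma_p.pop(tree.left[v]), sigma_p.pop(tree.right[v]))
            sm_ = _acc_add(sigma_m.pop(tree.left[v]), sigma_m.pop(tree.right[v]))
            if dv is not None:
                sp_ = _acc_sub(sp_, dv, p)
                sm_ = _acc_add(sm_, dv)
            sigma_p[v], sigma_m[v] = sp_, sm_
        if v == region_root:
            continue
        sp_, sm_ = sigma_p[v], sigma_m[v]
        par = tree.parent[v]
        yv = ycount[tree.right[par] if tree.left[par] == v else tree.left[par]]
        if yv == 0 or (sp_ is None and sm_ is None):
            continue
        xp = xi[par]
        if xp not in ppow_cache:
            ppow_cache[xp] = PowerVector.powers(xp, p).values
        xpow = ppow_cache[xp]
        svp = sp_.values if sp_ is not None else None
        svm = sm_.values if sm_ is not None else None
        acc = 0
        for l in range(p + 1):
            term = 0
            if svp is not None:
                term += xpow[l] * svp[p - l]
            if svm is not None:
                term += xpow[p - l] * svm[l]
            if term:
                acc += binoms[l] * term if (p - l) % 2 == 0 else -binoms[l] * term
        total += yv * acc
    return total


def _single_mixed_max(tree, xi, post, region_root, is_region_leaf, beta, ycount):
    # L-infinity: only the extreme beta values under each vertex matter
    lo: dict[int, object] = {}
    hi: dict[int, object] = {}
    best = None
    for v in post:
        if is_region_leaf(v):
            lab = tree.label[v]
            if lab in beta:
                lo[v] = hi[v] = beta[lab]
            else:
                lo[v] = hi[v] = None
        else:
            l, r = tree.left[v], tree.right[v]
            ls, rs = lo.pop(l), lo.pop(r)
            lo[v] = ls if rs is None else rs if ls is None else min(ls, rs)
            ls, rs = hi.pop(l), hi.pop(r)
            hi[v] = ls if rs is None else rs if ls is None else max(ls, rs)
        if v == region_root or lo[v] is None:
            continue
        par = tree.parent[v]
        yv = ycount[tree.right[par] if tree.left[par] == v else tree.left[par]]
        if yv == 0:
            continue
        xp = xi[par]
        cand = max(abs(xp - lo[v]), abs(xp - hi[v]))
        if best is None or cand > best:
            best = cand
    return best


def partial_single_mixed(
    at1: AnnotatedTree,
    at2: AnnotatedTree,
    sp1: MedianSplit,
    sp2: MedianSplit,
    p,
    variant: str,
):
    """Dispatch one of the four single-mixed partial distances.

    ``AA|A'B'`` sweeps the upper part of the first tree; ``BB|A'B'`` the
    lower part; the two remaining variants swap the roles of the trees.
    ``p`` may be INF, in which case the maximum (not the sum) over the
    variant's pair set is returned (None if the pair set is empty).
    """
    if variant not in SINGLE_MIXED_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant in ("AB|A'A'", "AB|B'B'"):
        at1, at2 = at2, at1
        sp1, sp2 = sp2, sp1
        region = "upper" if variant == "AB|A'A'" else "lower"
    else:
        region = "upper" if variant == "AA|A'B'" else "lower"
    own = sp1.A if region == "upper" else sp1.B
    beta = {lab: _beta_of(at2, sp2, lab) for lab in own & sp2.A}
    y_labels = own & sp2.B
    binoms = None if p == INF else binomials(p)
    return _single_mixed_region(at1, region, sp1.t, beta, y_labels, p, binoms)


# ---------------------------------------------------------------------------
# The unified recursion
# ---------------------------------------------------------------------------


def _diag_term(at1: AnnotatedTree, at2: AnnotatedTree, lab: str, p):
    d = abs(
        at1.xi[at1.tree.leaf_of_label(lab)] - at2.xi[at2.tree.leaf_of_label(lab)]
    )
    return d if p == INF else d ** p


def _base_power_sum(at1, at2, p):
    """Direct double loop for the tiny base-case trees (pure Python: the
    numpy set-up cost of the full oracle dominates at these sizes)."""
    t1, t2 = at1.tree, at2.tree
    labels = sorted(t1.leaf_labels)

    def chains(t):
        out = {}
        for lab in labels:
            v = t.leaf_of_label(lab)
            ch = []
            while v != NO_VERTEX:
                ch.append(v)
                v = t.parent[v]
            out[lab] = ch
        return out

    c1, c2 = chains(t1), chains(t2)

    def lca_xi(at, ch, a, b):
        if a == b:
            return at.xi[ch[a][0]]
        anc = set(ch[a])
        return at.xi[next(u for u in ch[b] if u in anc)]

    total = 0 if p != INF else None
    for i, a in enumerate(labels):
        for b in labels[i:]:
            d = abs(lca_xi(at1, c1, a, b) - lca_xi(at2, c2, a, b))
            if p == INF:
                total = d if total is None else max(total, d)
            else:
                total += d ** p
    return total


def _part_dist(at1, at2, p, binoms, base_threshold):
    n = at1.tree.n_leaves
    if n <= base_threshold:
        return _base_power_sum(at1, at2, p)
    t1, t2 = median_vertex(at1.tree), median_vertex(at2.tree)
    sp1, sp2 = split(at1.tree, t1), split(at2.tree, t2)

    s = 0
    # non-mixed: contract to each shared part and recurse
    for X in (sp1.A, sp1.B):
        for Xp in (sp2.A, sp2.B):
            K = X & Xp
            if not K:
                continue
            if len(K) == 1:
                s += _diag_term(at1, at2, next(iter(K)), p)
                continue
            s += _part_dist(
                contract(at1, K), contract(at2, K), p, binoms, base_threshold
            )
    s += partial_double_mixed_aligned(at1, at2, sp1, sp2, p)
    s += partial_double_mixed_crossed(at1, at2, sp1, sp2, p)
    for variant in SINGLE_MIXED_VARIANTS:
        s += partial_single_mixed(at1, at2, sp1, sp2, p, variant)
    return s


def _part_dist_inf(at1, at2, base_threshold):
    n = at1.tree.n_leaves
    if n <= base_threshold:
        return _base_power_sum(at1, at2, INF)
    t1, t2 = median_vertex(at1.tree), median_vertex(at2.tree)
    sp1, sp2 = split(at1.tree, t1), split(at2.tree, t2)

    best = None

    def take(x):
        nonlocal best
        if x is not None and (best is None or x > best):
            best = x

    for X in (sp1.A, sp1.B):
        for Xp in (sp2.A, sp2.B):
            K = X & Xp
            if not K:
                continue
            if len(K) == 1:
                take(_diag_term(at1, at2, next(iter(K)), INF))
                continue
            take(_part_dist_inf(contract(at1, K), contract(at2, K), base_threshold))

    if sp1.B & sp2.B:
        for lab in sp1.A & sp2.A:
            take(abs(_beta_of(at1, sp1, lab) - _beta_of(at2, sp2, lab)))
    take(
        _seq_max(
            get_cntr(at1, sp1, sp1.A & sp2.B), get_cntr(at2, sp2, sp1.B & sp2.A)
        )
    )
    for variant in SINGLE_MIXED_VARIANTS:
        take(partial_single_mixed(at1, at2, sp1, sp2, INF, variant))
    return best


def _prepare(at1: AnnotatedTree, at2: AnnotatedTree):
    check_pair(at1, at2)
    return as_descending(at1), as_descending(at2)


def coph_distance(
    at1: AnnotatedTree,
    at2: AnnotatedTree,
    p: int,
    *,
    base_threshold: int = BASE_THRESHOLD,
    float_p_cap: int = FLOAT_P_CAP,
) -> DistanceResult:
    """L_p cophenetic distance by the divide-and-conquer framework.

    Bit-exact against :func:`coph.naive.naive_distance` for integer-valued
    contributions at any p; for real-valued (weighted) contributions p is
    capped at ``float_p_cap`` to keep floating-point error controlled.
    """
    if not isinstance(p, int) or p < 1:
        raise ValueError("p must be an integer >= 1 (use coph_distance_inf for L-infinity)")
    d1, d2 = _prepare(at1, at2)
    if not (d1.integer_valued and d2.integer_valued) and p > float_p_cap:
        raise ValueError(
            f"p = {p} exceeds the cap ({float_p_cap}) for real-valued "
            f"contributions; exact arithmetic needs integer contributions"
        )
    binoms = binomials(p)
    ps = _part_dist(d1, d2, p, binoms, base_threshold)
    return DistanceResult.from_power_sum(p, ps)


def coph_distance_inf(
    at1: AnnotatedTree, at2: AnnotatedTree, *, base_threshold: int = BASE_THRESHOLD
) -> DistanceResult:
    """L-infinity cophenetic distance: the p = 1 recursion shape with every
    additive combination replaced by a maximum."""
    d1, d2 = _prepare(at1, at2)
    m = _part_dist_inf(d1, d2, base_threshold)
    return DistanceResult.from_power_sum(INF, m)
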
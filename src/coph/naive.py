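"""Quadratic reference computation of cophenetic vectors and L_p distances.

This is both a user-facing fallback and the correctness oracle for the
divide-and-conquer path.  Two routes are provided:

* :func:`cophenetic_vector` — a dict over leaf pairs built from per-leaf
  ancestor walks; deliberately simple enough to be obviously correct.
* :func:`naive_distance` — the same double loop evaluated through a dense
  lca-value matrix filled per internal vertex (numpy), with the power sum
  taken exactly over distinct integer differences when the contributions are
  integer-valued.  Exactness matters: at p = 100 the summands overflow any
  fixed-width float, and bit-exact agreement with the fast path is the
  headline contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contributions import AnnotatedTree, check_pair
from .treeio import NO_VERTEX, LabeledTree

__all__ = ["DistanceResult", "cophenetic_vector", "naive_distance"]

INF = math.inf


@dataclass(frozen=True)
class DistanceResult:
    """Result of a cophenetic distance computation.

    ``power_sum`` is sum |xi - xi'|^p over all leaf pairs (i <= j, diagonal
    included) for finite p — an exact int when both annotations are
    integer-valued — or max |xi - xi'| for p = infinity.  ``distance`` is
    power_sum^(1/p), or the max itself for the L-infinity norm.
    """

    p: float  # integer >= 1 or math.inf
    power_sum: object  # int | float
    distance: float

    @staticmethod
    def from_power_sum(p, power_sum) -> "DistanceResult":
        if p == INF:
            return DistanceResult(p=INF, power_sum=power_sum, distance=float(power_sum))
        if power_sum == 0:
            return DistanceResult(p=p, power_sum=power_sum, distance=0.0)
        # power_sum can exceed float range at large p; go through log space
        dist = math.exp(math.log(power_sum) / p)
        return DistanceResult(p=p, power_sum=power_sum, distance=dist)


def _ancestor_chain(tree: LabeledTree, v: int) -> list[int]:
    chain = []
    while v != NO_VERTEX:
        chain.append(v)
        v = tree.parent[v]
    return chain


def cophenetic_vector(at: AnnotatedTree, order: dict[str, int]) -> dict:
    """Cophenetic vector as a mapping (i, j), i <= j -> xi(lca(x_i, x_j)).

    lca via per-leaf ancestor chains; the diagonal entry (i, i) is xi(x_i).
    """
    tree = at.tree
    if set(order) != tree.leaf_labels:
        raise ValueError("ordering must cover exactly the leaf set")
    labels = sorted(order, key=order.get)
    chains = {lab: _ancestor_chain(tree, tree.leaf_of_label(lab)) for lab in labels}
    out = {}
    for i, la in enumerate(labels):
        anc_rank = {v: k for k, v in enumerate(chains[la])}
        for j in range(i, len(labels)):
            lb = labels[j]
            if i == j:
                lca = tree.leaf_of_label(la)
            else:
                lca = next(v for v in chains[lb] if v in anc_rank)
            out[(i, j)] = at.xi[lca]
    return out


def lca_value_matrix(at: AnnotatedTree, order: dict[str, int]) -> np.ndarray:
    """Dense n x n matrix M[i, j] = xi(lca(x_i, x_j)), filled one internal
    vertex at a time (all cross pairs of its two child subtrees)."""
    tree = at.tree
    n = tree.n_leaves
    integer = at.integer_valued
    M = np.zeros((n, n), dtype=np.int64 if integer else np.float64)
    leaf_sets: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            i = order[tree.label[v]]
            leaf_sets[v] = np.array([i], dtype=np.intp)
            M[i, i] = at.xi[v]
        else:
            li = leaf_sets.pop(tree.left[v])
            ri = leaf_sets.pop(tree.right[v])
            M[np.ix_(li, ri)] = at.xi[v]
            M[np.ix_(ri, li)] = at.xi[v]
            leaf_sets[v] = np.concatenate([li, ri])
    return M


def _power_sum_from_diffs(diffs: np.ndarray, p, integer: bool):
    """Sum |d|^p over the given differences; exact for integer input."""
    if p == INF:
        return int(diffs.max()) if integer else float(diffs.max()) if diffs.size else 0
    if integer:
        vals, counts = np.unique(diffs, return_counts=True)
        return sum(int(c) * int(v) ** p for v, c in zip(vals, counts))
    return float(np.sum(np.power(diffs.astype(np.float64), float(p))))


def naive_distance(at1: AnnotatedTree, at2: AnnotatedTree, p) -> DistanceResult:
    """Exact O(p n^2) cophenetic distance between two annotated trees over
    their (shared) lexicographic leaf ordering."""
    check_pair(at1, at2)
    if not (p == INF or (isinstance(p, int) and p >= 1)):
        raise ValueError("p must be an integer >= 1 or infinity")
    order = {lab: i for i, lab in enumerate(sorted(at1.tree.leaf_labels))}
    M1 = lca_value_matrix(at1, order)
    M2 = lca_value_matrix(at2, order)
    integer = at1.integer_valued and at2.integer_valued
    if not integer:
        M1 = M1.astype(np.float64)
        M2 = M2.astype(np.float64)
    iu = np.triu_indices(len(order))
    diffs = np.abs(M1[iu] - M2[iu])
    ps = _power_sum_from_diffs(diffs, p, integer)
    return DistanceResult.from_power_sum(p, ps)


def restricted_power_sum(at1: AnnotatedTree, at2: AnnotatedTree, p, pair_set) -> object:
    """Naive power sum (or max for p = inf) over an explicit set of unordered
    label pairs — the oracle for the per-category partial distances."""
    tree1, tree2 = at1.tree, at2.tree
    chains1 = {lab: _ancestor_chain(tree1, tree1.leaf_of_label(lab))
               for lab in tree1.leaf_labels}
    chains2 = {lab: _ancestor_chain(tree2, tree2.leaf_of_label(lab))
               for lab in tree2.leaf_labels}

    def lca_xi(at, chains, a, b):
        if a == b:
            return at.xi[at.tree.leaf_of_label(a)]
        anc = set(chains[a])
        v = next(u for u in chains[b] if u in anc)
        return at.xi[v]

    total = 0 if p != INF else -math.inf
    for a, b in pair_set:
        d = abs(lca_xi(at1, chains1, a, b) - lca_xi(at2, chains2, a, b))
        if p == INF:
            total = max(total, d)
        else:
            total += d ** p
    if p == INF and total == -math.inf:
        total = 0
    return total
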
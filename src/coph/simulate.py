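"""Seeded random tree generators and the distance-distribution experiment.

Two standard null models of rooted binary phylogenies are provided:

* ``yule`` — grow from a two-leaf cherry by repeatedly splitting a uniformly
  chosen leaf until n leaves, then assign the labels by a uniform random
  permutation;
* ``uniform`` — sequential insertion: leaf k+1 subdivides one of the 2k-1
  edge positions (counting a position above the root) chosen uniformly, which
  makes every one of the (2n-3)!! labeled topologies equally likely.

Generated trees are unweighted (contributions are counted in edges/leaves).
All randomness flows through an explicitly passed numpy Generator; identical
seeds give identical trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contributions import annotate
from .fastdist import coph_distance, coph_distance_inf
from .naive import INF
from .treeio import NO_VERTEX, LabeledTree

__all__ = ["SimulationConfig", "random_tree", "default_labels", "sample_distribution"]

MODELS = ("yule", "uniform")


def default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def _finish(parent, left, right, label, root) -> LabeledTree:
    return LabeledTree(parent=parent, left=left, right=right, label=label, root=root)


def _yule(n: int, rng: np.random.Generator, labels: list[str]) -> LabeledTree:
    nv = 2 * n - 1
    parent = [NO_VERTEX] * nv
    left = [NO_VERTEX] * nv
    right = [NO_VERTEX] * nv
    # root 0 with two leaf children 1, 2
    left[0], right[0] = 1, 2
    parent[1] = parent[2] = 0
    leaves = [1, 2]
    nxt = 3
    while len(leaves) < n:
        i = int(rng.integers(len(leaves)))
        v = leaves[i]
        a, b = nxt, nxt + 1
        nxt += 2
        left[v], right[v] = a, b
        parent[a] = parent[b] = v
        leaves[i] = a
        leaves.append(b)
    lab: list[str | None] = [None] * nv
    perm = rng.permutation(n)
    for leaf, j in zip(leaves, perm):
        lab[leaf] = labels[int(j)]
    return _finish(parent, left, right, lab, 0)


def _uniform(n: int, rng: np.random.Generator, labels: list[str]) -> LabeledTree:
    nv = 2 * n - 1
    parent = [NO_VERTEX] * nv
    left = [NO_VERTEX] * nv
    right = [NO_VERTEX] * nv
    lab: list[str | None] = [None] * nv
    # start from the single leaf carrying labels[0]
    root = 0
    lab[0] = labels[0]
    nxt = 1
    k = 1
    while k < n:
        # 2k - 1 positions: index of a non-root vertex's parent edge, or the
        # root position
        pos = int(rng.integers(2 * k - 1))
        new_leaf, new_int = nxt, nxt + 1
        nxt += 2
        lab[new_leaf] = labels[k]
        if pos == 2 * k - 2:  # above the root
            left[new_int], right[new_int] = root, new_leaf
            parent[root] = parent[new_leaf] = new_int
            root = new_int
        else:
            # enumerate non-root vertices in id order: ids 0..nxt-3 minus root
            v = pos if pos < root else pos + 1
            p = parent[v]
            if left[p] == v:
                left[p] = new_int
            else:
                right[p] = new_int
            parent[new_int] = p
            left[new_int], right[new_int] = v, new_leaf
            parent[v] = parent[new_leaf] = new_int
        k += 1
    return _finish(parent, left, right, lab, root)


def random_tree(
    model: str, n: int, rng: np.random.Generator, labels: list[str] | None = None
) -> LabeledTree:
    """Draw one random rooted binary tree with ``n`` labeled leaves."""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        labels = default_labels(n)
    if len(labels) != n or len(set(labels)) != n:
        raise ValueError("labels must be n distinct strings")
    if model == "yule":
        return _yule(n, rng, labels)
    if model == "uniform":
        return _uniform(n, rng, labels)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


# ---------------------------------------------------------------------------
# Distribution sampling
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Settings of a distance-distribution run."""

    model: str = "yule"
    n: int = 100
    q: int = 1000  # number of tree pairs
    seed: int = 0
    kinds: tuple[str, ...] = ("depth", "height", "size")
    p_values: tuple = (1, 2, INF)
    bins: int = 200

    def __post_init__(self):
        if self.n < 2 or self.q < 1:
            raise ValueError("need n >= 2 and q >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")


def sample_distribution(cfg: SimulationConfig):
    """Sample q independent tree pairs and tabulate every (kind, p) distance.

    Returns ``(rows, summary)``: rows are (kind, p, bin_lo, bin_hi, count) —
    equal-width bins over the observed range for finite p, exact integer
    frequencies for the L-infinity norm (integer contributions make those
    distances integers) — and summary rows are (kind, p, mean, sd).
    """
    rng = np.random.default_rng(cfg.seed)
    labels = default_labels(cfg.n)
    dists: dict[tuple, list[float]] = {
        (kind, p): [] for kind in cfg.kinds for p in cfg.p_values
    }
    for _ in range(cfg.q):
        t1 = random_tree(cfg.model, cfg.n, rng, labels)
        t2 = random_tree(cfg.model, cfg.n, rng, labels)
        for kind in cfg.kinds:
            a1, a2 = annotate(t1, kind), annotate(t2, kind)
            for p in cfg.p_values:
                if p == INF:
                    d = coph_distance_inf(a1, a2).distance
                else:
                    d = coph_distance(a1, a2, p).distance
                dists[(kind, p)].append(d)

    rows = []
    summary = []
    for (kind, p), vals in dists.items():
        arr = np.asarray(vals, dtype=float)
        summary.append((kind, p, float(arr.mean()), float(arr.std(ddof=0))))
        if p == INF:
            uniq, counts = np.unique(arr, return_counts=True)
            for v, c in zip(uniq, counts):
                rows.append((kind, p, float(v), float(v), int(c)))
        else:
            lo, hi = float(arr.min()), float(arr.max())
            if lo == hi:
                rows.append((kind, p, lo, hi, len(vals)))
                continue
            counts, edges = np.histogram(arr, bins=cfg.bins, range=(lo, hi))
            for b, c in enumerate(counts):
                if c:
                    rows.append((kind, p, float(edges[b]), float(edges[b + 1]), int(c)))
    return rows, summary


def format_p(p) -> str:
    return "inf" if p == INF else str(p)


def write_distribution_tsv(rows, summary, path_rows, path_summary=None) -> None:
    with open(path_rows, "w") as fh:
        fh.write("kind\tp\tbin_lo\tbin_hi\tcount\n")
        for kind, p, lo, hi, c in rows:
            fh.write(f"{kind}\t{format_p(p)}\t{lo:.10g}\t{hi:.10g}\t{c}\n")
    if path_summary is not None:
        with open(path_summary, "w") as fh:
            fh.write("kind\tp\tmean\tsd\n")
            for kind, p, mean, sd in summary:
                fh.write(f"{kind}\t{format_p(p)}\t{mean:.10g}\t{sd:.10g}\n")
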
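"""Structural toolkit of the divide-and-conquer: median vertices, upper/lower
splits, and lca-preserving contraction.

A median vertex t splits a rooted binary tree with n leaves into the lower
tree (the subtree at t, with n/4 <= |T_t| <= n/2 leaves) and the upper tree
(the tree with T_t replaced by a placeholder leaf, with n/2 <= |T^t| <=
3n/4 + 1 leaves).  It is found by descending from the root toward the child
with the larger subtree until the size drops to n/2 or below.

Contraction restricts a tree to a leaf subset, suppressing degree-2 vertices.
Crucially, each surviving vertex keeps the contribution value of the original
vertex it corresponds to (the original lca of its leaf set); contributions are
never recomputed on the contracted shape.  That is the correctness linchpin of
the recursion: for every surviving pair, xi_contracted(lca_contracted(x, y))
equals xi_original(lca_original(x, y)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .contributions import AnnotatedTree
from .treeio import NO_VERTEX, LabeledTree

__all__ = [
    "MedianSplit",
    "median_vertex",
    "median_vertex_candidates",
    "split",
    "contract",
    "EMPTY_TREE",
]


class _EmptyTree:
    """Sentinel for the contraction of a tree to the empty leaf set."""

    def __repr__(self) -> str:  # pragma: no cover
        return "EMPTY_TREE"


EMPTY_TREE = _EmptyTree()


def median_vertex(tree: LabeledTree) -> int:
    """Median vertex by the standard descent: start at the root, repeatedly
    step to the child with the larger subtree (ties break left) until the
    subtree size is at most n/2."""
    n = tree.n_leaves
    if n < 2:
        raise ValueError("median vertex requires a tree with at least 2 leaves")
    size = tree.subtree_leaf_counts()
    t = tree.root
    while 2 * size[t] > n:
        l, r = tree.left[t], tree.right[t]
        t = l if size[l] >= size[r] else r
    return t


def median_vertex_candidates(tree: LabeledTree) -> set[int]:
    """All vertices reachable by the median descent over every tie-breaking
    (the descent is deterministic except when the two children have equal
    subtree sizes)."""
    n = tree.n_leaves
    if n < 2:
        raise ValueError("median vertex requires a tree with at least 2 leaves")
    size = tree.subtree_leaf_counts()
    out: set[int] = set()
    frontier = [tree.root]
    while frontier:
        t = frontier.pop()
        if 2 * size[t] <= n:
            out.add(t)
            continue
        l, r = tree.left[t], tree.right[t]
        if size[l] >= size[r]:
            frontier.append(l)
        if size[r] >= size[l]:
            frontier.append(r)
    return out


@dataclass(frozen=True)
class MedianSplit:
    """A tree's median split.

    ``A``: labels of the upper-tree leaves (the placeholder leaf standing in
    for the lower tree is not a labeled leaf and is excluded); ``B``: labels
    of the leaves below t.  ``median_path`` runs root -> t inclusive.
    ``path_index`` maps each label in A to the index on the median path of
    lca(x, t) — for an upper leaf x that lca is the path vertex off which x's
    subtree hangs; for x in B it would be t itself.
    """

    t: int
    A: frozenset[str]
    B: frozenset[str]
    median_path: tuple[int, ...]
    path_index: dict[str, int]


def split(tree: LabeledTree, t: int) -> MedianSplit:
    """Split ``tree`` at vertex ``t`` (usually a median vertex)."""
    if t == tree.root:
        raise ValueError("cannot split at the root: the upper tree degenerates")
    below = set(tree.preorder(t))
    B = frozenset(tree.label[v] for v in below if tree.is_leaf(v))

    path = []
    v = t
    while v != NO_VERTEX:
        path.append(v)
        v = tree.parent[v]
    path.reverse()  # root ... t

    path_index: dict[str, int] = {}
    for i, m in enumerate(path[:-1]):
        off = tree.right[m] if path[i + 1] == tree.left[m] else tree.left[m]
        for u in tree.preorder(off):
            if tree.is_leaf(u):
                path_index[tree.label[u]] = i
    A = frozenset(path_index)
    return MedianSplit(t=t, A=A, B=B, median_path=tuple(path), path_index=path_index)


# ---------------------------------------------------------------------------
# Contraction
# ---------------------------------------------------------------------------


def _dfs_lca_sweep(tree: LabeledTree, kept_leaves: set[int]):
    """One DFS yielding entry/exit times, the kept leaves in DFS order, and
    the lca of each consecutive kept-leaf pair.

    Between two consecutive kept leaves the minimum-depth vertex touched by
    the walk (counting re-entries from a child, as in an Euler tour) is
    exactly their lca, so a running minimum suffices — no tour is stored.
    """
    n = tree.n_vertices
    tin = [0] * n
    tout = [0] * n
    depth = [0] * n
    left, right = tree.left, tree.right
    order: list[int] = []
    lcas: list[int] = []
    run_v = -1  # min-depth vertex since the previous kept leaf
    run_d = n + 1
    clock = 0
    stack: list[tuple[int, int]] = [(tree.root, 0)]  # (vertex, stage)
    while stack:
        v, stage = stack.pop()
        d = depth[v]
        if d < run_d:
            run_d, run_v = d, v
        if stage == 0:
            tin[v] = clock
            clock += 1
            if left[v] == NO_VERTEX:
                tout[v] = clock
                clock += 1
                if v in kept_leaves:
                    if order:
                        lcas.append(run_v)
                    order.append(v)
                    run_v, run_d = v, d
            else:
                depth[left[v]] = d + 1
                depth[right[v]] = d + 1
                stack.append((v, 2))
                stack.append((right[v], 0))
                stack.append((v, 1))
                stack.append((left[v], 0))
        elif stage == 2:
            tout[v] = clock
            clock += 1
    return tin, tout, order, lcas


def contract(at: AnnotatedTree, keep: Iterable[str]):
    """Restrict an annotated tree to the leaf-label set ``keep``.

    Returns :data:`EMPTY_TREE` for the empty set, a single annotated leaf for
    a singleton, and otherwise the induced binary topology whose vertices
    carry the ORIGINAL contribution values.
    """
    keep = set(keep)
    tree = at.tree
    missing = keep - tree.leaf_labels
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    if not keep:
        return EMPTY_TREE
    if len(keep) == 1:
        (lab,) = keep
        v = tree.leaf_of_label(lab)
        single = LabeledTree(
            parent=[NO_VERTEX], left=[NO_VERTEX], right=[NO_VERTEX],
            label=[lab], root=0,
        )
        return replace(at, tree=single, xi=(at.xi[v],), kind=at.kind)
    if keep == tree.leaf_labels:
        return at

    kept_set = {tree.leaf_of_label(lab) for lab in keep}
    tin, tout, kept, lcas = _dfs_lca_sweep(tree, kept_set)
    nodes = set(kept)
    nodes.update(lcas)
    ordered = sorted(nodes, key=lambda v: tin[v])

    # virtual-tree construction over (leaves ∪ consecutive lcas)
    new_id = {v: i for i, v in enumerate(ordered)}
    m = len(ordered)
    parent = [NO_VERTEX] * m
    children: list[list[int]] = [[] for _ in range(m)]
    stack: list[int] = []
    for v in ordered:
        while stack and not (tin[stack[-1]] <= tin[v] and tout[v] <= tout[stack[-1]]):
            stack.pop()
        if stack:
            parent[new_id[v]] = new_id[stack[-1]]
            children[new_id[stack[-1]]].append(new_id[v])
        stack.append(v)

    left = [NO_VERTEX] * m
    right = [NO_VERTEX] * m
    label: list[str | None] = [None] * m
    for v in ordered:
        i = new_id[v]
        ch = children[i]
        if not ch:
            label[i] = tree.label[v]
        elif len(ch) == 2:
            left[i], right[i] = ch
        else:  # pragma: no cover — cannot happen for binary input
            raise AssertionError("contraction produced a non-binary vertex")

    root_new = new_id[ordered[0]]
    ctree = LabeledTree(
        parent=parent, left=left, right=right, label=label, root=root_new
    )
    xi = tuple(at.xi[v] for v in ordered)
    # `ordered` is sorted by tin so ordered[i] has new id i; xi lines up
    return replace(at, tree=ctree, xi=xi, kind=at.kind)
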
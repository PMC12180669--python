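"""Per-vertex contribution functions and path-monotonicity handling.

A contribution function assigns a value xi(v) to every vertex; the cophenetic
vector of a tree collects xi at the least common ancestor of every leaf pair.
Three combinatorial contributions are supported (depth, subtree height,
subtree leaf count) plus weighted depth/height for trees with branch lengths.

Depth grows away from the root (descending, in the path-monotone sense that
descendants carry values >= their ancestors' after orienting by the root);
height and size shrink away from the root (ascending).  The divide-and-conquer
algorithms assume the descending orientation, so ascending annotations are
normalized by negation — which preserves every pairwise |xi - xi'| exactly and
keeps integer-valuedness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .treeio import NO_VERTEX, LabeledTree

__all__ = ["AnnotatedTree", "ContributionError", "annotate", "as_descending", "KINDS"]

KINDS = ("depth", "height", "size", "weighted_depth", "weighted_height")

_DIRECTION = {
    "depth": "descending",
    "weighted_depth": "descending",
    "height": "ascending",
    "size": "ascending",
}


class ContributionError(ValueError):
    """Invalid contribution request (e.g. weighted kind on unweighted tree)."""


@dataclass(frozen=True)
class AnnotatedTree:
    """A tree plus a path-monotone per-vertex contribution.

    ``xi[v]`` is the contribution of vertex v; ``direction`` records which way
    it is monotone along every root-to-leaf path; ``integer_valued`` is True
    iff every value is an exact integer (then all downstream arithmetic is
    exact).
    """

    tree: LabeledTree
    xi: tuple
    direction: str  # "ascending" | "descending"
    integer_valued: bool
    kind: str = "custom"

    def check_monotone(self) -> bool:
        """Verify the declared direction on every parent edge."""
        t = self.tree
        for v in range(t.n_vertices):
            p = t.parent[v]
            if p == NO_VERTEX:
                continue
            if self.direction == "descending":
                if not self.xi[v] >= self.xi[p]:
                    return False
            else:
                if not self.xi[v] <= self.xi[p]:
                    return False
        return True


def _depths(tree: LabeledTree, weighted: bool):
    xi = [0] * tree.n_vertices
    if weighted:
        w = tree.edge_weight
        root_w = tree.root_edge_weight or 0
        xi = [0.0] * tree.n_vertices
        xi[tree.root] = root_w
        for v in tree.preorder():
            if v != tree.root:
                xi[v] = xi[tree.parent[v]] + w[v]
    else:
        for v in tree.preorder():
            if v != tree.root:
                xi[v] = xi[tree.parent[v]] + 1
    return xi


def _heights(tree: LabeledTree, weighted: bool):
    # height of the subtree at v: longest downward path, in edges or weight.
    # The optional rooting edge lies outside every subtree and is ignored.
    xi = [0.0 if weighted else 0] * tree.n_vertices
    w = tree.edge_weight
    for v in tree.postorder():
        if not tree.is_leaf(v):
            l, r = tree.left[v], tree.right[v]
            if weighted:
                xi[v] = max(xi[l] + w[l], xi[r] + w[r])
            else:
                xi[v] = max(xi[l], xi[r]) + 1
    return xi


def _sizes(tree: LabeledTree):
    return tree.subtree_leaf_counts()


def annotate(tree: LabeledTree, kind: str) -> AnnotatedTree:
    """Annotate every vertex with the requested contribution.

    ``kind`` is one of ``depth``, ``height``, ``size``, ``weighted_depth``,
    ``weighted_height``.  ``size`` counts leaves and ignores weights even on
    weighted trees.  For weighted depth, an optional rooting-edge weight is
    added to every vertex's depth.
    """
    if kind not in KINDS:
        raise ContributionError(f"unknown contribution kind: {kind!r}")
    weighted = kind.startswith("weighted_")
    if weighted and tree.edge_weight is None:
        raise ContributionError(f"{kind} requested but the tree has no branch lengths")
    if kind in ("depth", "weighted_depth"):
        xi = _depths(tree, weighted)
    elif kind in ("height", "weighted_height"):
        xi = _heights(tree, weighted)
    else:
        xi = _sizes(tree)
    base = kind.removeprefix("weighted_")
    integer = all(float(x).is_integer() for x in xi) if weighted else True
    if integer:
        xi = [int(x) for x in xi]
    return AnnotatedTree(
        tree=tree,
        xi=tuple(xi),
        direction=_DIRECTION[base],
        integer_valued=integer,
        kind=kind,
    )


def annotate_custom(
    tree: LabeledTree, fn: Callable[[LabeledTree, int], float], direction: str
) -> AnnotatedTree:
    """Hook for user-supplied contributions; only the per-edge monotonicity
    of the declared direction is checked."""
    if direction not in ("ascending", "descending"):
        raise ContributionError("direction must be 'ascending' or 'descending'")
    xi = [fn(tree, v) for v in range(tree.n_vertices)]
    integer = all(isinstance(x, int) or float(x).is_integer() for x in xi)
    if integer:
        xi = [int(x) for x in xi]
    at = AnnotatedTree(
        tree=tree, xi=tuple(xi), direction=direction, integer_valued=integer
    )
    if not at.check_monotone():
        raise ContributionError(
            f"supplied contribution is not {direction} on every parent edge"
        )
    return at


def as_descending(at: AnnotatedTree) -> AnnotatedTree:
    """Normalize to the descending orientation by negation (identity if
    already descending).  Applied jointly to both trees of a pair this leaves
    every |xi(u) - xi'(u')| unchanged."""
    if at.direction == "descending":
        return at
    return replace(
        at, xi=tuple(-x for x in at.xi), direction="descending"
    )


def check_pair(at1: AnnotatedTree, at2: AnnotatedTree) -> None:
    """Validate that two annotated trees are comparable: same leaf set and
    same monotonicity direction (mixed kinds of one direction are allowed,
    mixed directions are not)."""
    if at1.tree.leaf_labels != at2.tree.leaf_labels:
        diff = sorted(at1.tree.leaf_labels ^ at2.tree.leaf_labels)
        raise ValueError(
            f"trees have different leaf sets; symmetric difference: "
            f"{{{', '.join(diff)}}}"
        )
    if at1.direction != at2.direction:
        raise ValueError(
            f"contribution directions differ ({at1.kind}: {at1.direction} vs "
            f"{at2.kind}: {at2.direction}); pair two ascending or two "
            f"descending contributions"
        )
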
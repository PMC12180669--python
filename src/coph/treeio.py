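"""Rooted binary trees with labeled leaves, and Newick I/O.

Trees are stored in flat arrays indexed by integer vertex ids; every internal
vertex has exactly a left and a right child, so a tree with n leaves has
2n - 1 vertices.  Parsing and serialization go through dendropy; validation
(binarity, label uniqueness) is enforced here because the distance algorithms
depend on it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "LabeledTree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "shared_leaf_index",
]

NO_VERTEX = -1


class NewickError(ValueError):
    """Raised on malformed or unsupported Newick input."""


@dataclass
class LabeledTree:
    """A rooted binary tree with uniquely labeled leaves.

    Vertices are integers ``0 .. 2n-2``.  ``left[v] == NO_VERTEX`` iff v is a
    leaf.  ``edge_weight[v]`` is the weight of the edge above v (None if the
    tree is unweighted); ``root_edge_weight`` is the optional weight of an
    extra rooting edge hanging above the root.
    """

    parent: list[int]
    left: list[int]
    right: list[int]
    label: list[str | None]  # None for internal vertices
    root: int
    edge_weight: list[float] | None = None
    root_edge_weight: float | None = None
    _leaf_of_label: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._leaf_of_label:
            self._leaf_of_label = {
                lab: v for v, lab in enumerate(self.label) if lab is not None
            }

    # -- basic queries -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return (self.n_vertices + 1) // 2

    def is_leaf(self, v: int) -> bool:
        return self.left[v] == NO_VERTEX

    def leaves(self) -> list[int]:
        return [v for v in range(self.n_vertices) if self.is_leaf(v)]

    def leaf_of_label(self, lab: str) -> int:
        return self._leaf_of_label[lab]

    @property
    def leaf_labels(self) -> set[str]:
        return set(self._leaf_of_label)

    def sibling(self, v: int) -> int:
        p = self.parent[v]
        if p == NO_VERTEX:
            raise ValueError("root has no sibling")
        return self.right[p] if self.left[p] == v else self.left[p]

    # -- traversals (iterative: caterpillar trees exceed the Python
    #    recursion limit well before they stress these algorithms) ------

    def preorder(self, start: int | None = None) -> list[int]:
        root = self.root if start is None else start
        out: list[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            out.append(v)
            if not self.is_leaf(v):
                stack.append(self.right[v])
                stack.append(self.left[v])
        return out

    def postorder(self, start: int | None = None) -> list[int]:
        # visit parent, right, left; the reversal yields left, right, parent
        root = self.root if start is None else start
        out: list[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            out.append(v)
            if not self.is_leaf(v):
                stack.append(self.left[v])
                stack.append(self.right[v])
        out.reverse()
        return out

    def leaves_under(self, v: int) -> list[int]:
        return [u for u in self.preorder(v) if self.is_leaf(u)]

    def subtree_leaf_counts(self) -> list[int]:
        size = [0] * self.n_vertices
        for v in self.postorder():
            size[v] = 1 if self.is_leaf(v) else size[self.left[v]] + size[self.right[v]]
        return size

    def depths(self) -> list[int]:
        d = [0] * self.n_vertices
        for v in self.preorder():
            p = self.parent[v]
            if p != NO_VERTEX:
                d[v] = d[p] + 1
        return d

    def leaves_in_dfs_order(self) -> list[int]:
        return [v for v in self.preorder() if self.is_leaf(v)]


# ---------------------------------------------------------------------------
# Newick I/O via dendropy
# ---------------------------------------------------------------------------


def _from_dendropy(dt: dendropy.Tree) -> LabeledTree:
    nodes = list(dt.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = [NO_VERTEX] * n
    left = [NO_VERTEX] * n
    right = [NO_VERTEX] * n
    label: list[str | None] = [None] * n
    weights: list[float] = [0.0] * n
    any_weight = False

    for i, nd in enumerate(nodes):
        ch = nd.child_nodes()
        if len(ch) == 0:
            lab = None
            if nd.taxon is not None:
                lab = nd.taxon.label
            elif nd.label is not None:
                lab = nd.label
            if lab is None or lab == "":
                raise NewickError("leaf without a label")
            label[i] = lab
        elif len(ch) == 2:
            left[i] = index[id(ch[0])]
            right[i] = index[id(ch[1])]
            parent[index[id(ch[0])]] = i
            parent[index[id(ch[1])]] = i
        else:
            members = sorted(
                lf.taxon.label if lf.taxon else str(lf.label)
                for lf in nd.leaf_iter()
            )
            raise NewickError(
                f"non-binary vertex with {len(ch)} children over clade "
                f"{{{', '.join(members)}}}: only binary trees are supported"
            )
        if nd.edge.length is not None and nd.parent_node is not None:
            weights[i] = float(nd.edge.length)
            any_weight = True

    labels_seen = [lab for lab in label if lab is not None]
    if len(labels_seen) != len(set(labels_seen)):
        dupes = sorted({x for x in labels_seen if labels_seen.count(x) > 1})
        raise NewickError(f"duplicate leaf label(s): {', '.join(dupes)}")

    root_edge = None
    root_nd = nodes[0]
    if root_nd.edge.length is not None:
        root_edge = float(root_nd.edge.length)

    tree = LabeledTree(
        parent=parent,
        left=left,
        right=right,
        label=label,
        root=0,
        edge_weight=weights if any_weight else None,
        root_edge_weight=root_edge,
    )
    if any_weight:
        # mixing weighted and unweighted edges silently would corrupt the
        # weighted contributions; demand all-or-nothing
        for v in range(n):
            if v != tree.root and nodes[v].edge.length is None:
                raise NewickError(
                    "tree mixes weighted and unweighted branches; "
                    "give every branch a length or none"
                )
    return tree


def parse_newick(text: str) -> LabeledTree:
    """Parse a single rooted binary Newick tree.

    Branch lengths, if present on every edge, populate ``edge_weight``; a
    length on the outermost group populates ``root_edge_weight``.  Internal
    node labels are ignored.  Raises :class:`NewickError` for malformed
    input, non-binary vertices or duplicate leaf labels.
    """
    if not text.strip().endswith(";"):
        raise NewickError("Newick string must be terminated by ';'")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    if dt.seed_node is None or len(dt.seed_node.child_nodes()) == 0 and dt.seed_node.taxon is None:
        raise NewickError("empty tree")
    return _from_dendropy(dt)


_UNQUOTED_OK = set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.-")


def _fmt_label(lab: str) -> str:
    if lab and all(c in _UNQUOTED_OK for c in lab):
        return lab
    return "'" + lab.replace("'", "''") + "'"


def _fmt_weight(w: float) -> str:
    if float(w).is_integer():
        return str(int(w))
    return repr(float(w))


def write_newick(tree: LabeledTree) -> str:
    """Serialize a :class:`LabeledTree` back to Newick.

    ``parse_newick(write_newick(t))`` is isomorphic to ``t`` with identical
    labels and weights.
    """
    parts: dict[int, str] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            s = _fmt_label(tree.label[v])  # type: ignore[arg-type]
        else:
            s = f"({parts.pop(tree.left[v])},{parts.pop(tree.right[v])})"
        if tree.edge_weight is not None and v != tree.root:
            s += f":{_fmt_weight(tree.edge_weight[v])}"
        parts[v] = s
    s = parts[tree.root]
    if tree.root_edge_weight is not None:
        s += f":{_fmt_weight(tree.root_edge_weight)}"
    return s + ";"


def shared_leaf_index(t1: LabeledTree, t2: LabeledTree) -> dict[str, int]:
    """Common leaf ordering for a tree pair: label -> index, lexicographic.

    The cophenetic vector is defined over a *fixed* leaf ordering shared by
    both trees; lexicographic order makes it machine-independent.  Raises if
    the leaf sets differ, listing the symmetric difference.
    """
    s1, s2 = t1.leaf_labels, t2.leaf_labels
    if s1 != s2:
        diff = sorted(s1 ^ s2)
        raise ValueError(
            f"trees have different leaf sets; symmetric difference: "
            f"{{{', '.join(diff)}}}"
        )
    return {lab: i for i, lab in enumerate(sorted(s1))}
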
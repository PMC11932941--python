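"""Newick input/output and the unrooted gene-tree structure.

Gene trees are leaf-labeled unrooted trees: internal nodes have degree >= 3
(degree-2 nodes, including roots of rooted inputs, are suppressed on parse),
polytomies are allowed, and each tree may be missing taxa from the global
taxon universe.  Branch lengths, support values and internal labels are
accepted and discarded -- the method is topology-only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy


class NewickParseError(ValueError):
    """Raised for malformed Newick input."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


# ---------------------------------------------------------------------------
# Rooted utility tree (used for species-tree output and internal rooted views)
# ---------------------------------------------------------------------------


class Node:
    """Rooted tree node; leaves carry a label (taxon string or a dummy object)."""

    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        stack, out = [self], []
        while stack:
            v = stack.pop()
            if v.is_leaf:
                out.append(v)
            else:
                stack.extend(reversed(v.children))
        return out

    def leaf_labels(self):
        return [v.label for v in self.leaves()]

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({write_newick(self).rstrip(';')})"


def write_newick(root: Node) -> str:
    """Serialize a rooted tree to a Newick string (topology only)."""

    def rec(v: Node) -> str:
        if v.is_leaf:
            return _quote_label(str(v.label))
        return "(" + ",".join(rec(c) for c in v.children) + ")"

    return rec(root) + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in "();,:[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Unrooted gene tree
# ---------------------------------------------------------------------------


@dataclass
class UnrootedGeneTree:
    """Unrooted leaf-labeled tree stored as an adjacency structure.

    ``adjacency[i]`` lists the neighbors of node ``i``; ``leaf_labels`` maps
    leaf node ids to taxon labels.  Internal nodes all have degree >= 3
    (except in degenerate trees with < 3 leaves, which carry no quartet
    information and are retained only for completeness).
    """

    adjacency: list[list[int]]
    leaf_labels: dict[int, str]
    tree_index: int = 0
    _label_set: frozenset[str] | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.adjacency)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def labels(self) -> frozenset[str]:
        if self._label_set is None:
            object.__setattr__(self, "_label_set", frozenset(self.leaf_labels.values()))
        return self._label_set

    def degree(self, node: int) -> int:
        return len(self.adjacency[node])

    def internal_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if v not in self.leaf_labels]

    def has_polytomy(self) -> bool:
        return any(len(self.adjacency[v]) > 3 for v in self.internal_nodes())

    # -- conversions --------------------------------------------------------

    def to_rooted(self, root: int | None = None) -> Node:
        """Return a rooted :class:`Node` view (root defaults to an internal node)."""
        if root is None:
            internals = self.internal_nodes()
            root = internals[0] if internals else next(iter(self.leaf_labels))
        nodes = {v: Node(self.leaf_labels.get(v)) for v in range(self.n_nodes)}
        seen = {root}
        stack = [root]
        while stack:
            v = stack.pop()
            for w in self.adjacency[v]:
                if w not in seen:
                    seen.add(w)
                    nodes[v].children.append(nodes[w])
                    stack.append(w)
        return nodes[root]

    def nontrivial_bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """All splits induced by internal edges, each as {side1, side2}."""
        all_labels = self.labels()
        out = set()
        for side in self._edge_sides():
            other = all_labels - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset((frozenset(side), other)))
        return out

    def _edge_sides(self):
        """Leaf set on the child side of every edge of a rooted traversal."""
        root = self.internal_nodes()[0] if self.internal_nodes() else 0
        order, parent = _dfs_order(self.adjacency, root)
        sides = {}
        for v in reversed(order):
            s = {self.leaf_labels[v]} if v in self.leaf_labels else set()
            for w in self.adjacency[v]:
                if w != parent.get(v) and w in sides:
                    s |= sides[w]
            sides[v] = s
        return [frozenset(sides[v]) for v in order if v != root]


def _dfs_order(adjacency, root):
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adjacency[v]:
            if w != parent[v]:
                parent[w] = v
                stack.append(w)
    return order, parent


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> list[UnrootedGeneTree]:
    """Parse a multi-tree Newick string into unrooted gene trees.

    One tree per semicolon-terminated statement.  Branch lengths, internal
    labels and comments are discarded; rooted inputs are read as unrooted
    (a degree-2 root is suppressed); quoted labels are supported and
    unquoted underscores are kept verbatim.
    """
    statements = [s.strip() for s in text.split(";") if s.strip()]
    trees: list[UnrootedGeneTree] = []
    for idx, stmt in enumerate(statements):
        try:
            dtree = dendropy.Tree.get(
                data=stmt + ";",
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon label" in str(exc) or "Multiple occurrences" in str(exc):
                raise TreeValidationError(
                    f"tree {idx + 1}: duplicate leaf label: {exc}") from exc
            raise NewickParseError(f"malformed Newick in tree {idx + 1}: {exc}") from exc
        trees.append(_from_dendropy(dtree, idx))
    if not trees:
        raise NewickParseError("no trees found in input")
    return trees


def _from_dendropy(dtree: "dendropy.Tree", tree_index: int) -> UnrootedGeneTree:
    # Build undirected adjacency, then suppress degree-2 nodes (incl. root).
    dnodes = list(dtree.preorder_node_iter())
    ids = {id(nd): i for i, nd in enumerate(dnodes)}
    adjacency: list[list[int]] = [[] for _ in dnodes]
    labels: dict[int, str] = {}
    for nd in dnodes:
        i = ids[id(nd)]
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise NewickParseError(
                    f"tree {tree_index + 1}: leaf without a label"
                )
            labels[i] = nd.taxon.label
        for ch in nd.child_nodes():
            j = ids[id(ch)]
            adjacency[i].append(j)
            adjacency[j].append(i)
    seen: set[str] = set()
    for lab in labels.values():
        if lab in seen:
            raise TreeValidationError(
                f"tree {tree_index + 1}: duplicate leaf label {lab!r}"
            )
        seen.add(lab)
    return _suppress_degree_two(adjacency, labels, tree_index)


def _suppress_degree_two(adjacency, labels, tree_index) -> UnrootedGeneTree:
    n = len(adjacency)
    removed = [False] * n
    for v in range(n):
        if v in labels:
            continue
        if len(adjacency[v]) == 2:
            a, b = adjacency[v]
            adjacency[a] = [b if x == v else x for x in adjacency[a]]
            adjacency[b] = [a if x == v else x for x in adjacency[b]]
            adjacency[v] = []
            removed[v] = True
        elif len(adjacency[v]) == 1 and n > 1:
            # Unlabeled pendant internal node (cannot arise from valid Newick).
            raise TreeValidationError(f"tree {tree_index + 1}: unlabeled pendant node")
    # compact node ids
    remap = {}
    new_adj: list[list[int]] = []
    new_labels: dict[int, str] = {}
    for v in range(n):
        if removed[v]:
            continue
        remap[v] = len(new_adj)
        new_adj.append([])
    for v in range(n):
        if removed[v]:
            continue
        new_adj[remap[v]] = [remap[w] for w in adjacency[v]]
        if v in labels:
            new_labels[remap[v]] = labels[v]
    return UnrootedGeneTree(new_adj, new_labels, tree_index)


def rooted_to_unrooted(root: Node, tree_index: int = 0) -> UnrootedGeneTree:
    """Convert a rooted :class:`Node` tree to an :class:`UnrootedGeneTree`."""
    adjacency: list[list[int]] = []
    labels: dict[int, str] = {}

    def add(v: Node) -> int:
        i = len(adjacency)
        adjacency.append([])
        if v.is_leaf:
            labels[i] = str(v.label)
        for c in v.children:
            j = add(c)
            adjacency[i].append(j)
            adjacency[j].append(i)
        return i

    add(root)
    return _suppress_degree_two(adjacency, labels, tree_index)


def read_gene_trees(path) -> list[UnrootedGeneTree]:
    """Read a multi-tree Newick file (one tree per statement)."""
    with io.open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Taxon universe and RF distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonUniverse:
    """The ordered set X of all labels across the input, with n = |X|, k trees."""

    labels: tuple[str, ...]
    k: int

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_trees(cls, trees: list[UnrootedGeneTree]) -> "TaxonUniverse":
        seen: dict[str, None] = {}
        for t in trees:
            for lab in sorted(t.labels()):
                seen.setdefault(lab, None)
        return cls(tuple(sorted(seen)), len(trees))


def robinson_foulds(t1, t2) -> float:
    """Normalized Robinson-Foulds distance in [0, 1] between two trees.

    Accepts rooted :class:`Node` trees or :class:`UnrootedGeneTree`s; rooted
    trees are compared as unrooted topologies.  The symmetric difference of
    non-trivial bipartitions is divided by the total number of non-trivial
    bipartitions of both trees (0 when both trees are stars).
    """
    u1 = t1 if isinstance(t1, UnrootedGeneTree) else rooted_to_unrooted(t1)
    u2 = t2 if isinstance(t2, UnrootedGeneTree) else rooted_to_unrooted(t2)
    if u1.labels() != u2.labels():
        raise ValueError("trees have different leaf sets")
    b1 = u1.nontrivial_bipartitions()
    b2 = u2.nontrivial_bipartitions()
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom
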
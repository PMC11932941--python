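"""Divide-and-conquer driver: from gene trees to a species tree.

Each divide step bipartitions the current item set S with the consensus
seed plus FM refinement, wraps each side in a fresh dummy taxon handed to
the opposite subproblem, recurses, and splices the two rooted solutions
together at the dummy leaves.  Subproblems of at most three items are
quartet-indistinguishable and become rooted stars.  The output is written
rooted as produced by the recursion but should be read as an unrooted
topology (quartet-based summary methods estimate unrooted trees).

With fully resolved gene trees and balanced subproblems the whole
procedure runs in O(n^3 k log n) time for n taxa and k gene trees; this is
a documented contract of the design, not an asserted bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import consensus as consensus_mod
from .dummy import (DummyStructure, check_normalization, coverage,
                    leaf_weights, make_dummy, sort_items)
from .fm import DEFAULT_MAX_PASSES, refine
from .scoring import Bipartition, ScoringSession
from .treeio import (Node, TaxonUniverse, UnrootedGeneTree, rooted_to_unrooted,
                     write_newick)


@dataclass
class EngineOptions:
    resolve_polytomies: bool = False
    seed: int = 0
    max_passes: int = DEFAULT_MAX_PASSES
    check_invariants: bool = True


@dataclass
class Subproblem:
    """An item set with its recursion depth and provenance."""

    items: tuple
    depth: int = 0
    parent_bipartition: Bipartition | None = None

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(sort_items(self.items)))
        covs = [coverage(it) for it in self.items]
        union = set()
        for c in covs:
            if union & c:
                raise ValueError("subproblem items cover overlapping taxa")
            union |= c


def divide(sub: Subproblem, bipartition: Bipartition) -> tuple[Subproblem, Subproblem, DummyStructure, DummyStructure]:
    """Split a subproblem along (A, B) into A u {X1} and B u {X2}.

    X1 wraps the items of B (so the A-side subproblem still "sees" the rest
    of the taxa through it) and X2 wraps the items of A; nested dummies
    appear as subtrees of the new dummies' structures.
    """
    if not bipartition.A or not bipartition.B:
        raise AssertionError("divide requires two non-empty sides")
    x1 = make_dummy(bipartition.B)
    x2 = make_dummy(bipartition.A)
    left = Subproblem(bipartition.A + (x1,), sub.depth + 1, bipartition)
    right = Subproblem(bipartition.B + (x2,), sub.depth + 1, bipartition)
    return left, right, x1, x2


def merge(left: Node, right: Node, x1: DummyStructure, x2: DummyStructure) -> Node:
    """Splice the two solved subtrees, eliminating this level's dummies.

    The dummy leaf X1 in the left tree stands for everything on the B side,
    so it is replaced by the right tree re-rooted at its X2 leaf (X2, which
    stands for the A side, disappears in the process).
    """
    attachment = _reroot_at_leaf(right, x2)
    replaced = _replace_leaf(left, x1, attachment)
    if not replaced:
        raise ValueError("dummy leaf missing from left subtree")
    return left


def _replace_leaf(root: Node, label, subtree: Node) -> bool:
    stack = [root]
    while stack:
        v = stack.pop()
        for i, c in enumerate(v.children):
            if c.is_leaf and c.label is label:
                v.children[i] = subtree
                return True
            stack.append(c)
    if root.is_leaf and root.label is label:
        raise ValueError("cannot replace the root leaf in place")
    return False


def _reroot_at_leaf(root: Node, leaf_label) -> Node:
    """Reorient a rooted tree at the given leaf and drop that leaf.

    Returns the subtree hanging from the leaf's former neighbor; single
    -child nodes produced by the reversal are suppressed.
    """
    parents: dict[int, Node] = {}
    target = None
    stack = [root]
    while stack:
        v = stack.pop()
        for c in v.children:
            parents[id(c)] = v
            if c.is_leaf and c.label is leaf_label:
                target = c
            else:
                stack.append(c)
    if target is None:
        if root.is_leaf and root.label is leaf_label:
            raise ValueError("dummy leaf is the whole subtree")
        raise ValueError("dummy leaf missing from right subtree")
    # reverse parent pointers along the path root -> target
    path = [target]
    while path[-1] is not root:
        path.append(parents[id(path[-1])])
    new_root = path[1]  # target's parent becomes the apex
    for child, par in zip(path, path[1:]):
        par.children = [c for c in par.children if c is not child]
    for par, child in zip(path[1:], path[2:]):
        par.children.append(child)
    return _suppress_unary(new_root)


def _suppress_unary(v: Node) -> Node:
    while not v.is_leaf and len(v.children) == 1:
        v = v.children[0]
    if not v.is_leaf:
        v.children = [_suppress_unary(c) for c in v.children]
    return v


class Engine:
    """Orchestrates consensus seeding, FM refinement and the recursion."""

    def __init__(self, gene_trees: list[UnrootedGeneTree],
                 options: EngineOptions | None = None):
        self.options = options or EngineOptions()
        self.rng = np.random.default_rng(self.options.seed)
        if self.options.resolve_polytomies:
            gene_trees = [resolve_polytomies_arbitrarily(t, self.rng)
                          for t in gene_trees]
        self.gene_trees = gene_trees
        self.universe = TaxonUniverse.from_trees(gene_trees)
        self.consensus = None

    def run(self) -> Node:
        if not self.gene_trees:
            raise ValueError("need at least one gene tree")
        taxa = self.universe.labels
        if len(taxa) == 0:
            raise ValueError("gene trees contain no taxa")
        if len(taxa) <= 3:
            return Node(None, [Node(t) for t in taxa]) if len(taxa) > 1 \
                else Node(taxa[0])
        self.consensus = consensus_mod.greedy_consensus(self.gene_trees)
        root = self._solve(Subproblem(tuple(taxa)))
        out_labels = sorted(root.leaf_labels())
        if list(out_labels) != sorted(taxa):
            raise AssertionError("output leaf set differs from taxon universe")
        return root

    def run_newick(self) -> str:
        return write_newick(self.run())

    # -- recursion ----------------------------------------------------------

    def _solve(self, sub: Subproblem) -> Node:
        items = sub.items
        if sub.depth > len(self.universe.labels) + 2:
            raise AssertionError("recursion depth exceeded taxon count")
        if len(items) == 1:
            it = items[0]
            return Node(it)
        if len(items) <= 3:
            return Node(None, [Node(it) for it in items])
        weights = leaf_weights(items)
        if self.options.check_invariants:
            check_normalization(items, weights)
        session = ScoringSession(self.gene_trees, weights)
        init = consensus_mod.initial_bipartition(
            items, self.consensus, self.gene_trees, weights, session=session)
        refined = refine(init, self.gene_trees, weights,
                         max_passes=self.options.max_passes, session=session)
        left_sub, right_sub, x1, x2 = divide(sub, refined)
        left = self._solve(left_sub)   # A side first, for determinism
        right = self._solve(right_sub)
        merged = merge(left, right, x1, x2)
        return merged


def resolve_polytomies_arbitrarily(tree: UnrootedGeneTree,
                                   rng: np.random.Generator) -> UnrootedGeneTree:
    """Resolve every polytomy into a random caterpillar (a speed option).

    Binary inputs pass through unchanged (identical topology).
    """
    if not tree.has_polytomy():
        return tree
    root = tree.to_rooted()

    def resolve(v: Node):
        for c in v.children:
            resolve(c)
        limit = 3 if v is root else 2
        if len(v.children) > limit:
            kids = list(v.children)
            order = rng.permutation(len(kids))
            kids = [kids[i] for i in order]
            acc = kids[0]
            for nxt in kids[1:len(kids) - (limit - 1)]:
                acc = Node(None, [acc, nxt])
            v.children = [acc] + kids[len(kids) - (limit - 1):]

    resolve(root)
    return rooted_to_unrooted(root, tree.tree_index)


def run(gene_trees: list[UnrootedGeneTree],
        options: EngineOptions | None = None) -> Node:
    """Infer a species tree from unrooted (possibly non-binary, possibly
    incomplete) gene trees; returns the rooted result tree."""
    return Engine(gene_trees, options).run()
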
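"""Brute-force quartet enumeration: the ground truth for the scoring engine.

Enumerates every 4-subset of every gene tree's taxa, restricts the tree to
those four leaves to get the induced quartet topology, classifies it against
the bipartition (sharing :func:`wqfmtree.scoring.classify_quartet` with the
production scorer, and nothing else), and accumulates exact Fraction
weights.  Theta(n^4) per tree; guarded to small n -- this is test
scaffolding, not a production path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

from .dummy import WeightAssignment
from .scoring import Bipartition, QuartetClass, classify_quartet
from .treeio import UnrootedGeneTree, _dfs_order

ORACLE_MAX_N = 14


def induced_topology(tree: UnrootedGeneTree, taxa):
    """Topology of the quartet induced by ``tree`` on four taxa.

    Returns a pair of 2-tuples ``((a, b), (c, d))`` when some branch
    separates {a, b} from {c, d}, or ``None`` when the restriction is a
    star (unresolved).  Equivalent to restricting the tree to the four
    leaves and suppressing degree-2 nodes.
    """
    taxa = tuple(taxa)
    if len(set(taxa)) != 4:
        raise ValueError("need four distinct taxa")
    label_to_node = {lab: v for v, lab in tree.leaf_labels.items()}
    for t in taxa:
        if t not in label_to_node:
            raise ValueError(f"taxon {t!r} missing from tree")
    a, b, c, d = taxa
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    for pair1, pair2 in pairings:
        path1 = _path_nodes(tree, label_to_node[pair1[0]], label_to_node[pair1[1]])
        path2 = _path_nodes(tree, label_to_node[pair2[0]], label_to_node[pair2[1]])
        if not (path1 & path2):
            return pair1, pair2
    return None


def _path_nodes(tree: UnrootedGeneTree, u: int, v: int) -> frozenset:
    order, parent = _dfs_order(tree.adjacency, u)
    path = [v]
    while path[-1] != u:
        path.append(parent[path[-1]])
    return frozenset(path)


@dataclass
class OracleScore:
    """Exact per-class weight totals from full enumeration."""

    wS: Fraction
    wV: Fraction
    wU: Fraction
    n_satisfied: int
    n_violated: int
    n_deferred: int
    n_excluded: int
    n_unresolved: int

    @property
    def wSVU(self) -> Fraction:
        return self.wS + self.wV + self.wU

    @property
    def score(self) -> Fraction:
        return self.wS - self.wV


def oracle_score_tree(tree: UnrootedGeneTree, bipartition: Bipartition,
                      weights: WeightAssignment) -> OracleScore:
    """Enumerate and classify all quartets of one gene tree."""
    fa = bipartition.FA
    fb = bipartition.FB
    relevant = sorted(lab for lab in tree.labels() if lab in fa or lab in fb)
    if len(relevant) > ORACLE_MAX_N:
        raise ValueError(
            f"oracle refuses n={len(relevant)} (guarded at {ORACLE_MAX_N})")
    dummy_of = weights.dummy_id_of
    wS = wV = wU = Fraction(0)
    counts = dict.fromkeys(QuartetClass, 0)
    for quad in itertools.combinations(relevant, 4):
        topology = induced_topology(tree, quad)
        cls = classify_quartet(quad, topology, fa, dummy_of)
        counts[cls] += 1
        if cls in (QuartetClass.SATISFIED, QuartetClass.VIOLATED,
                   QuartetClass.UNRESOLVED):
            wq = Fraction(1)
            for t in quad:
                wq *= weights.weight[t]
            if cls is QuartetClass.SATISFIED:
                wS += wq
            elif cls is QuartetClass.VIOLATED:
                wV += wq
            else:
                wU += wq
    return OracleScore(wS, wV, wU,
                       counts[QuartetClass.SATISFIED],
                       counts[QuartetClass.VIOLATED],
                       counts[QuartetClass.DEFERRED],
                       counts[QuartetClass.EXCLUDED],
                       counts[QuartetClass.UNRESOLVED])


def oracle_score(bipartition: Bipartition, gene_trees,
                 weights: WeightAssignment):
    """Aggregate enumeration score over gene trees.

    Returns ``(per_tree, total_score)`` where ``per_tree`` is a list of
    :class:`OracleScore` and ``total_score`` the exact Fraction
    sum over trees of w(S(g)) - w(V(g)).
    """
    per_tree = [oracle_score_tree(g, bipartition, weights) for g in gene_trees]
    total = sum((o.score for o in per_tree), Fraction(0))
    return per_tree, total


def anchor_decomposition(tree: UnrootedGeneTree, bipartition: Bipartition,
                         weights: WeightAssignment) -> dict[int, Fraction]:
    """Per-anchor-node satisfied weights, by explicit assignment.

    Each satisfied resolved quartet is assigned to the internal node
    adjacent to its A-side pair: the unique node u whose removal puts the
    two A-side taxa in distinct components and the B-side pair together in
    a third.  Raises if a satisfied quartet has no anchor or several (the
    decomposition must be a partition).
    """
    fa = bipartition.FA
    fb = bipartition.FB
    relevant = sorted(lab for lab in tree.labels() if lab in fa or lab in fb)
    if len(relevant) > ORACLE_MAX_N:
        raise ValueError("oracle guard exceeded")
    dummy_of = weights.dummy_id_of
    label_to_node = {lab: v for v, lab in tree.leaf_labels.items()}
    per_node: dict[int, Fraction] = {}
    for quad in itertools.combinations(relevant, 4):
        topology = induced_topology(tree, quad)
        if classify_quartet(quad, topology, fa, dummy_of) is not QuartetClass.SATISFIED:
            continue
        pair1, pair2 = topology
        a_pair = pair1 if pair1[0] in fa else pair2
        b_pair = pair2 if a_pair is pair1 else pair1
        anchors = []
        for u in tree.internal_nodes():
            comp = _components_of(tree, u)
            ca0 = comp[label_to_node[a_pair[0]]]
            ca1 = comp[label_to_node[a_pair[1]]]
            cb0 = comp[label_to_node[b_pair[0]]]
            cb1 = comp[label_to_node[b_pair[1]]]
            if ca0 != ca1 and cb0 == cb1 and cb0 not in (ca0, ca1):
                anchors.append(u)
        if len(anchors) != 1:
            raise AssertionError(
                f"satisfied quartet {quad} has {len(anchors)} anchors, expected 1")
        wq = Fraction(1)
        for t in quad:
            wq *= weights.weight[t]
        per_node[anchors[0]] = per_node.get(anchors[0], Fraction(0)) + wq
    return per_node


def _components_of(tree: UnrootedGeneTree, u: int) -> dict[int, int]:
    """Map every node != u to the index of its component when u is removed."""
    comp = {}
    for i, start in enumerate(tree.adjacency[u]):
        stack = [start]
        comp[start] = i
        while stack:
            v = stack.pop()
            for w in tree.adjacency[v]:
                if w != u and w not in comp:
                    comp[w] = i
                    stack.append(w)
    return comp
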
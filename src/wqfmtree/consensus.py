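"""Greedy (majority-rule extended) consensus and initial bipartitions.

The divide step needs a starting bipartition of each subproblem.  One
consensus tree of the full gene-tree input is computed once and reused: all
non-trivial splits of the gene trees are counted, sorted by decreasing
frequency, and inserted greedily into a star tree over the taxon universe
whenever the insertion keeps a valid tree.  Each consensus edge, projected
onto the subproblem (real items follow their side; a dummy follows the side
holding the larger weighted share of its covered taxa, ties to side B), is
a candidate; the highest-scoring projection seeds the FM refinement.

Incomplete gene trees contribute partial splits.  A tree counts toward a
split's frequency denominator only when it is informative for it (at least
two of the split's taxa on each side present in the tree); insertion pulls
unconstrained taxa along with the cluster they nest inside, which for
complete inputs reduces exactly to the classical majority-rule extended
consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dummy import DummyStructure, WeightAssignment, coverage, sort_items
from .scoring import Bipartition, ScoringSession
from .treeio import Node, UnrootedGeneTree, rooted_to_unrooted, write_newick


@dataclass(frozen=True)
class _Split:
    """A (possibly partial) unrooted split with its occurrence frequency."""

    side1: frozenset[str]
    side2: frozenset[str]
    count: int
    informative: int

    @property
    def frequency(self) -> float:
        return self.count / self.informative if self.informative else 0.0


@dataclass
class ConsensusTree:
    """Consensus topology over the taxon universe with per-edge frequencies.

    ``edges`` lists, for every internal edge, the full bipartition of the
    taxon universe it induces together with the frequency of the gene-tree
    split that created it.  ``candidates`` keeps the full sorted candidate
    split list for fallback use.
    """

    root: Node
    taxa: frozenset[str]
    edges: list[tuple[frozenset[str], frozenset[str], float]]
    candidates: list[_Split]

    def to_newick(self) -> str:
        return write_newick(self.root)

    def to_unrooted(self) -> UnrootedGeneTree:
        return rooted_to_unrooted(self.root)


def _collect_splits(trees: list[UnrootedGeneTree]) -> list[_Split]:
    counts: dict[tuple, int] = {}
    tree_labels = [t.labels() for t in trees]
    for t in trees:
        for bip in t.nontrivial_bipartitions():
            s1, s2 = sorted(bip, key=lambda s: (len(s), sorted(s)))
            counts[(s1, s2)] = counts.get((s1, s2), 0) + 1
    splits = []
    for (s1, s2), c in counts.items():
        informative = sum(
            1 for labs in tree_labels
            if len(s1 & labs) >= 2 and len(s2 & labs) >= 2
        )
        splits.append(_Split(s1, s2, c, max(informative, 1)))
    # decreasing frequency; ties: higher raw count, smaller small side,
    # lexicographically smallest small side (full determinism)
    splits.sort(key=lambda s: (
        -s.frequency, -s.count, len(s.side1), sorted(s.side1), sorted(s.side2)))
    return splits


class _CTree:
    """Mutable rooted tree over the taxon universe used during insertion."""

    def __init__(self, taxa):
        self.root = Node(None, [Node(t) for t in sorted(taxa)])
        self.freq: dict[int, float] = {}  # id(node) -> frequency of its edge

    def leafsets(self):
        sets: dict[int, frozenset] = {}

        def rec(v: Node) -> frozenset:
            if v.is_leaf:
                s = frozenset((v.label,))
            else:
                s = frozenset().union(*(rec(c) for c in v.children))
            sets[id(v)] = s
            return s

        rec(self.root)
        return sets

    def try_insert(self, cluster: frozenset, other: frozenset, freq: float) -> bool:
        """Try to create an edge separating ``cluster`` from ``other``.

        Unconstrained taxa nested inside grouped children are pulled into
        the cluster.  Returns True when the tree displays the split after
        the call (including when it already did).
        """
        sets = self.leafsets()
        # locate the lowest node whose leaf set contains the cluster
        v = self.root
        while True:
            nxt = None
            for c in v.children:
                if not c.is_leaf and cluster <= sets[id(c)]:
                    nxt = c
                    break
            if nxt is None:
                break
            v = nxt
        group = [c for c in v.children if sets[id(c)] & cluster]
        if any(sets[id(c)] & other for c in group):
            return False
        if len(group) == len(v.children) and v is self.root:
            return False
        if len(group) == len(v.children):
            # the edge above v already separates the grouped leaves
            return not (sets[id(v)] & other)
        if len(group) <= 1:
            # cluster confined to a single child: already displayed there or
            # not separable at this node
            return bool(group) and not (sets[id(group[0])] & other)
        w = Node(None, group)
        v.children = [c for c in v.children if c not in group] + [w]
        self.freq[id(w)] = freq
        return True


def greedy_consensus(trees: list[UnrootedGeneTree]) -> ConsensusTree:
    """Majority-rule extended consensus of the input gene trees.

    Splits are added in order of decreasing frequency (frequency computed
    over trees informative for the split) whenever the growing tree can
    display them; every split above 50% frequency on complete inputs is
    therefore included, and all accepted splits are pairwise compatible.
    """
    if not trees:
        raise ValueError("need at least one gene tree")
    taxa = frozenset().union(*(t.labels() for t in trees))
    candidates = _collect_splits(trees)
    ct = _CTree(taxa)
    for sp in candidates:
        # try the smaller side as the cluster first, then the other
        for cluster, other in ((sp.side1, sp.side2), (sp.side2, sp.side1)):
            if ct.try_insert(cluster, other, sp.frequency):
                break
    edges = []
    sets = ct.leafsets()
    for v, parent in _internal_edges(ct.root):
        side = sets[id(v)]
        edges.append((side, taxa - side, ct.freq.get(id(v), 0.0)))
    return ConsensusTree(ct.root, taxa, edges, candidates)


def _internal_edges(root: Node):
    out = []

    def rec(v: Node):
        for c in v.children:
            if not c.is_leaf:
                out.append((c, v))
                rec(c)

    rec(root)
    return out


# ---------------------------------------------------------------------------
# Projection onto a subproblem
# ---------------------------------------------------------------------------


def project_bipartition(side_a: frozenset[str], side_b: frozenset[str],
                        items, weights: WeightAssignment) -> Bipartition:
    """Project a full-taxon-set bipartition onto a subproblem's items.

    Real items follow their side; a dummy goes to side A only when the
    weighted share of its covered taxa on side A strictly exceeds the share
    on side B (an exact tie goes to side B).
    """
    A, B = [], []
    for it in sort_items(items):
        if isinstance(it, DummyStructure):
            wa = sum(weights.weight[a] for a in it.xr if a in side_a)
            wb = sum(weights.weight[a] for a in it.xr if a in side_b)
            (A if wa > wb else B).append(it)
        else:
            if it in side_a:
                A.append(it)
            elif it in side_b:
                B.append(it)
            else:
                raise AssertionError(f"item {it!r} on neither side of the split")
    return Bipartition(tuple(A), tuple(B))


def _degenerate(bip: Bipartition, n_items: int) -> bool:
    if not bip.A or not bip.B:
        return True
    if n_items > 3 and min(len(bip.A), len(bip.B)) == 1:
        return True
    return False


def initial_bipartition(items, consensus: ConsensusTree, gene_trees,
                        weights: WeightAssignment,
                        session: ScoringSession | None = None) -> Bipartition:
    """Best-scoring projection of a consensus edge onto the subproblem.

    Degenerate projections (an empty side, or a singleton side when the
    subproblem has more than three items) are skipped.  If no consensus
    edge yields a usable projection, candidate gene-tree splits are tried
    in frequency order; as a last resort the items are halved in stable
    order.  Always returns a bipartition with two non-empty sides.
    """
    items = tuple(sort_items(items))
    n = len(items)
    if session is None:
        session = ScoringSession(gene_trees, weights)
    best: Bipartition | None = None
    best_score = float("-inf")
    for side_a, side_b, _freq in consensus.edges:
        bip = project_bipartition(side_a, side_b, items, weights)
        if _degenerate(bip, n):
            continue
        s = session.score_of(bip)
        if s > best_score:
            best, best_score = bip, s
    if best is not None:
        return best
    covered = frozenset().union(*(coverage(it) for it in items))
    for sp in consensus.candidates:
        side1 = sp.side1 & covered
        side2 = (sp.side2 & covered) | (covered - sp.side1 - sp.side2)
        if not side1 or not side2:
            continue
        bip = project_bipartition(side1, side2, items, weights)
        if not _degenerate(bip, n):
            return bip
    half = n // 2
    return Bipartition(items[:half], items[half:])
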
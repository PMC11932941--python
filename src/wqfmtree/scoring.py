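"""Bipartition scoring computed directly from gene trees.

For a candidate bipartition (A, B) of a subproblem, every induced quartet
ab|cd of every gene tree falls into one class: *satisfied* (both pairs split
cleanly across the two sides), *violated* (two taxa per side but mispaired),
*deferred* (three or more of the four taxa on one side), or *excluded* (two
of the four taxa lie under the same dummy taxon of the current subproblem,
which must act as a single taxon).  Unresolved quartets of non-binary trees
with two taxa per side form the set U.  The bipartition score is

    Score(A, B, G) = sum_g [ w(S(g)) - w(V(g)) ]
                   = sum_g [ 2 w(S(g)) - w(S(g) u V(g) u U(g)) + w(U(g)) ]

with quartet weight w(ab|cd) = w(a) w(b) w(c) w(d) from the per-subproblem
leaf weights.  The three terms are computed without enumerating quartets:

* w(S(g)) decomposes over internal nodes u ("anchors"): a satisfied quartet
  is counted exactly once, at the node where its A-side pair sits in two
  distinct components and its B-side pair together in a third.  Per-node
  sums reduce to pair-weight aggregates of component weight sums, with
  same-dummy pairs removed via per-dummy subtotals.
* w(S u V u U) = w(PA(g)) * w(PB(g)), the product of the dummy-excluded
  pair weights of the two sides within the tree's taxon set.
* w(U(g)) is accumulated over polytomy nodes only, from cross-component
  pair weights of both sides.

The quartet-free path is exercised against the brute-force enumeration
oracle (see :mod:`wqfmtree.oracle`) to 1e-9.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from numba import njit

from .dummy import DummyStructure, WeightAssignment, coverage, sort_items
from .treeio import UnrootedGeneTree, _dfs_order

# ---------------------------------------------------------------------------
# Bipartition of a subproblem
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A bipartition (A, B) of a subproblem's items.

    ``A`` and ``B`` are tuples of items (real taxon labels or
    :class:`~wqfmtree.dummy.DummyStructure`).  ``FA``/``FB`` are the real
    taxa covered by each side.
    """

    A: tuple
    B: tuple

    def __post_init__(self):
        object.__setattr__(self, "A", tuple(sort_items(self.A)))
        object.__setattr__(self, "B", tuple(sort_items(self.B)))

    @property
    def RA(self):
        return tuple(x for x in self.A if not isinstance(x, DummyStructure))

    @property
    def DA(self):
        return tuple(x for x in self.A if isinstance(x, DummyStructure))

    @property
    def RB(self):
        return tuple(x for x in self.B if not isinstance(x, DummyStructure))

    @property
    def DB(self):
        return tuple(x for x in self.B if isinstance(x, DummyStructure))

    @property
    def FA(self) -> frozenset[str]:
        out = set()
        for x in self.A:
            out |= coverage(x)
        return frozenset(out)

    @property
    def FB(self) -> frozenset[str]:
        out = set()
        for x in self.B:
            out |= coverage(x)
        return frozenset(out)

    def swap(self) -> "Bipartition":
        return Bipartition(self.B, self.A)

    def move(self, item) -> "Bipartition":
        """Return the bipartition with ``item`` transferred to the other side."""
        if item in self.A:
            if len(self.A) == 1:
                raise ValueError("move would empty side A")
            return Bipartition(tuple(x for x in self.A if x is not item),
                               self.B + (item,))
        if item in self.B:
            if len(self.B) == 1:
                raise ValueError("move would empty side B")
            return Bipartition(self.A + (item,),
                               tuple(x for x in self.B if x is not item))
        raise ValueError(f"item {item!r} not in bipartition")


# ---------------------------------------------------------------------------
# Quartet classification (shared with the enumeration oracle)
# ---------------------------------------------------------------------------


class QuartetClass(enum.Enum):
    SATISFIED = "satisfied"
    VIOLATED = "violated"
    DEFERRED = "deferred"
    EXCLUDED = "excluded"
    UNRESOLVED = "unresolved"  # two taxa per side, no separating branch: in U


def classify_quartet(taxa, topology, fa: frozenset, dummy_of) -> QuartetClass:
    """Classify one quartet of four distinct real taxa against a bipartition.

    ``topology`` is a pair of 2-tuples ``({a, b}, {c, d})`` for a resolved
    quartet ab|cd, or ``None`` if no branch of the gene tree separates two
    of the taxa from the other two.  ``fa`` is the covered taxon set of side
    A; ``dummy_of`` maps a taxon to the id of its covering dummy (or -1).

    A quartet with two taxa under the same current-subproblem dummy is
    excluded outright (a dummy contributes at most once per quartet); with
    three or more taxa on one side it is deferred; otherwise a resolved
    quartet is satisfied when its topology pairs coincide with the sides,
    violated when they do not, and an unresolved quartet belongs to U.
    """
    ids = [dummy_of(t) for t in taxa]
    for i in range(4):
        for j in range(i + 1, 4):
            if ids[i] >= 0 and ids[i] == ids[j]:
                return QuartetClass.EXCLUDED
    on_a = sum(1 for t in taxa if t in fa)
    if on_a >= 3 or on_a <= 1:
        return QuartetClass.DEFERRED
    if topology is None:
        return QuartetClass.UNRESOLVED
    p, q = topology
    p_in_a = sum(1 for t in p if t in fa)
    if p_in_a in (0, 2):  # pairs align with the sides
        return QuartetClass.SATISFIED
    return QuartetClass.VIOLATED


# ---------------------------------------------------------------------------
# Flat per-tree structure for the kernel
# ---------------------------------------------------------------------------


class _TreeStruct:
    """Static flat-array view of one gene tree, independent of any bipartition.

    Leaves are laid out in DFS (Euler) order so that every rooted subtree is
    a contiguous interval; each internal node's components (child subtrees
    plus, off the root, the complement) become rows of a component table.
    """

    __slots__ = ("leaf_taxa", "comp_lo", "comp_hi", "comp_is_compl",
                 "node_ptr", "n_internal")

    def __init__(self, tree: UnrootedGeneTree):
        internals = tree.internal_nodes()
        adj = tree.adjacency
        if not internals or tree.n_leaves < 2:
            self.leaf_taxa = [tree.leaf_labels[v] for v in sorted(tree.leaf_labels)]
            self.comp_lo = np.zeros(0, np.int64)
            self.comp_hi = np.zeros(0, np.int64)
            self.comp_is_compl = np.zeros(0, np.bool_)
            self.node_ptr = np.zeros(1, np.int64)
            self.n_internal = 0
            return
        root = internals[0]
        order, parent = _dfs_order(adj, root)
        lo = {}
        hi = {}
        leaf_taxa: list[str] = []
        # DFS with explicit post-processing to get contiguous intervals
        for v in _preorder(adj, root, parent):
            lo[v] = len(leaf_taxa)
            if v in tree.leaf_labels:
                leaf_taxa.append(tree.leaf_labels[v])
        # hi = lo + subtree leaf count, computed in reverse topological order
        count = {v: (1 if v in tree.leaf_labels else 0) for v in order}
        for v in reversed(order):
            for w in adj[v]:
                if parent.get(w) == v:
                    count[v] += count[w]
        for v in order:
            hi[v] = lo[v] + count[v]
        comp_lo, comp_hi, comp_is_compl, node_ptr = [], [], [], [0]
        for u in internals:
            for w in adj[u]:
                if parent.get(w) == u:
                    comp_lo.append(lo[w])
                    comp_hi.append(hi[w])
                    comp_is_compl.append(False)
            if u != root:
                comp_lo.append(lo[u])
                comp_hi.append(hi[u])
                comp_is_compl.append(True)
            node_ptr.append(len(comp_lo))
        self.leaf_taxa = leaf_taxa
        self.comp_lo = np.asarray(comp_lo, np.int64)
        self.comp_hi = np.asarray(comp_hi, np.int64)
        self.comp_is_compl = np.asarray(comp_is_compl, np.bool_)
        self.node_ptr = np.asarray(node_ptr, np.int64)
        self.n_internal = len(internals)


def _preorder(adj, root, parent):
    out = []
    stack = [root]
    while stack:
        v = stack.pop()
        out.append(v)
        children = [w for w in adj[v] if parent.get(w) == v]
        stack.extend(reversed(children))
    return out


_STRUCT_CACHE_ATTR = "_wqfm_struct"


def tree_struct(tree: UnrootedGeneTree) -> _TreeStruct:
    cached = getattr(tree, _STRUCT_CACHE_ATTR, None)
    if cached is None:
        cached = _TreeStruct(tree)
        setattr(tree, _STRUCT_CACHE_ATTR, cached)
    return cached


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------


@njit(cache=False, fastmath=False)
def _score_tree_kernel(w, w2, side, dummy, n_dummy,
                       comp_lo, comp_hi, comp_is_compl, node_ptr):
    """Return (wS, wSVU, wU) for one gene tree under one side assignment.

    ``w``/``w2`` are per-leaf weights and squared weights (0 for taxa not in
    the subproblem), ``side`` is 1 on side A and 0 on side B, ``dummy`` is
    the compact covering-dummy index in [0, n_dummy) or -1.
    """
    L = w.shape[0]
    D = n_dummy
    ca = np.zeros(L + 1)
    ca2 = np.zeros(L + 1)
    cb = np.zeros(L + 1)
    cb2 = np.zeros(L + 1)
    cad = np.zeros((L + 1, D))
    cbd = np.zeros((L + 1, D))
    cb2d = np.zeros((L + 1, D))
    qad = np.zeros(D)  # global sum of w^2 on side A per dummy
    for i in range(L):
        wa = w[i] if side[i] == 1 else 0.0
        wb = w[i] if side[i] == 0 else 0.0
        wa2 = w2[i] if side[i] == 1 else 0.0
        wb2 = w2[i] if side[i] == 0 else 0.0
        ca[i + 1] = ca[i] + wa
        ca2[i + 1] = ca2[i] + wa2
        cb[i + 1] = cb[i] + wb
        cb2[i + 1] = cb2[i] + wb2
        for d in range(D):
            cad[i + 1, d] = cad[i, d]
            cbd[i + 1, d] = cbd[i, d]
            cb2d[i + 1, d] = cb2d[i, d]
        di = dummy[i]
        if di >= 0:
            cad[i + 1, di] += wa
            cbd[i + 1, di] += wb
            cb2d[i + 1, di] += wb2
            qad[di] += wa2
    TA = ca[L]
    QA = ca2[L]
    TB = cb[L]
    QB = cb2[L]

    # w(S u V u U) = w(PA(g)) * w(PB(g)), same-dummy pairs excluded
    pa_g = 0.5 * (TA * TA - QA)
    pb_g = 0.5 * (TB * TB - QB)
    for d in range(D):
        pa_g -= 0.5 * (cad[L, d] * cad[L, d] - qad[d])
        pb_g -= 0.5 * (cbd[L, d] * cbd[L, d] - cb2d[L, d])
    w_svu = pa_g * pb_g

    n_internal = node_ptr.shape[0] - 1
    max_comp = 0
    for u in range(n_internal):
        nc = node_ptr[u + 1] - node_ptr[u]
        if nc > max_comp:
            max_comp = nc
    sa = np.empty(max_comp)
    sb = np.empty(max_comp)
    qb = np.empty(max_comp)
    sad = np.empty((max_comp, D))
    sbd = np.empty((max_comp, D))
    qbd = np.empty((max_comp, D))

    w_s = 0.0
    w_u = 0.0
    for u in range(n_internal):
        s0 = node_ptr[u]
        nc = node_ptr[u + 1] - s0
        for c in range(nc):
            lo = comp_lo[s0 + c]
            hi = comp_hi[s0 + c]
            if comp_is_compl[s0 + c]:
                sa[c] = TA - (ca[hi] - ca[lo])
                sb[c] = TB - (cb[hi] - cb[lo])
                qb[c] = QB - (cb2[hi] - cb2[lo])
                for d in range(D):
                    sad[c, d] = cad[L, d] - (cad[hi, d] - cad[lo, d])
                    sbd[c, d] = cbd[L, d] - (cbd[hi, d] - cbd[lo, d])
                    qbd[c, d] = cb2d[L, d] - (cb2d[hi, d] - cb2d[lo, d])
            else:
                sa[c] = ca[hi] - ca[lo]
                sb[c] = cb[hi] - cb[lo]
                qb[c] = cb2[hi] - cb2[lo]
                for d in range(D):
                    sad[c, d] = cad[hi, d] - cad[lo, d]
                    sbd[c, d] = cbd[hi, d] - cbd[lo, d]
                    qbd[c, d] = cb2d[hi, d] - cb2d[lo, d]
        # P = sum_{i<j} w(PA_ij): A-side pairs split across two components
        p_u = TA * TA
        for c in range(nc):
            p_u -= sa[c] * sa[c]
        p_u *= 0.5
        for d in range(D):
            td = cad[L, d]
            corr = td * td
            for c in range(nc):
                corr -= sad[c, d] * sad[c, d]
            p_u -= 0.5 * corr
        node_s = 0.0
        for c in range(nc):
            # w(PB_c): B-side pairs within component c
            pbw = 0.5 * (sb[c] * sb[c] - qb[c])
            for d in range(D):
                pbw -= 0.5 * (sbd[c, d] * sbd[c, d] - qbd[c, d])
            if pbw != 0.0:
                # R_c = sum_{j != c} w(PA_cj)
                r_c = sa[c] * (TA - sa[c])
                for d in range(D):
                    r_c -= sad[c, d] * (cad[L, d] - sad[c, d])
                node_s += pbw * (p_u - r_c)
        w_s += node_s
        if nc >= 4:
            # unresolved quartets anchored at this polytomy node
            pbp = TB * TB
            for c in range(nc):
                pbp -= sb[c] * sb[c]
            pbp *= 0.5
            for d in range(D):
                td = cbd[L, d]
                corr = td * td
                for c in range(nc):
                    corr -= sbd[c, d] * sbd[c, d]
                pbp -= 0.5 * corr
            node_u = p_u * pbp
            for c in range(nc):
                r_c = sa[c] * (TA - sa[c])
                pbr_c = sb[c] * (TB - sb[c])
                for d in range(D):
                    r_c -= sad[c, d] * (cad[L, d] - sad[c, d])
                    pbr_c -= sbd[c, d] * (cbd[L, d] - sbd[c, d])
                node_u -= r_c * pbr_c
            # + sum_{i<j} w(PA_ij) w(PB_ij) (pairs straddling the same two comps)
            for i in range(nc):
                for j in range(i + 1, nc):
                    pa_ij = sa[i] * sa[j]
                    pb_ij = sb[i] * sb[j]
                    for d in range(D):
                        pa_ij -= sad[i, d] * sad[j, d]
                        pb_ij -= sbd[i, d] * sbd[j, d]
                    node_u += pa_ij * pb_ij
            w_u += node_u
    return w_s, w_svu, w_u


# ---------------------------------------------------------------------------
# Scoring session and public API
# ---------------------------------------------------------------------------


@dataclass
class ScoreParts:
    """Per-gene-tree weight triples and the aggregate bipartition score."""

    wS: np.ndarray
    wSVU: np.ndarray
    wU: np.ndarray

    @property
    def total(self) -> float:
        return float(np.sum(2.0 * self.wS - self.wSVU + self.wU))


class ScoringSession:
    """Reusable scorer for one subproblem (fixed gene trees and weights).

    Precomputes flat leaf arrays per gene tree; scoring a bipartition or a
    single-item transfer then only toggles side bits.  The accumulation
    order (tree order, then node order) is fixed for reproducibility.
    """

    def __init__(self, gene_trees, weights: WeightAssignment):
        self.gene_trees = list(gene_trees)
        self.weights = weights
        dummies = sorted(
            {id_ for id_ in (weights.dummy_id_of(a) for a in weights.weight) if id_ >= 0}
        )
        self._dummy_index = {d: i for i, d in enumerate(dummies)}
        self.n_dummy = len(dummies)
        self._trees = []
        for t in self.gene_trees:
            st = tree_struct(t)
            L = len(st.leaf_taxa)
            w = np.zeros(L)
            dum = np.full(L, -1, np.int64)
            relevant = []
            for i, tax in enumerate(st.leaf_taxa):
                fw = weights.float_weight.get(tax)
                if fw is not None:
                    w[i] = fw
                    did = weights.dummy_id_of(tax)
                    if did >= 0:
                        dum[i] = self._dummy_index[did]
                    relevant.append(i)
            side = np.zeros(L, np.int8)
            leaf_index = {}
            for i in relevant:
                leaf_index.setdefault(st.leaf_taxa[i], i)
            self._trees.append((st, w, w * w, side, dum, leaf_index))

    def set_bipartition(self, bipartition: Bipartition):
        fa = bipartition.FA
        for st, w, w2, side, dum, leaf_index in self._trees:
            side[:] = 0
            for tax, i in leaf_index.items():
                if tax in fa:
                    side[i] = 1

    def _flip(self, item):
        cov = coverage(item)
        for st, w, w2, side, dum, leaf_index in self._trees:
            for tax in cov:
                i = leaf_index.get(tax)
                if i is not None:
                    side[i] = 1 - side[i]

    def score_parts(self) -> ScoreParts:
        k = len(self._trees)
        wS = np.zeros(k)
        wSVU = np.zeros(k)
        wU = np.zeros(k)
        for g, (st, w, w2, side, dum, _) in enumerate(self._trees):
            if st.n_internal == 0 or len(st.leaf_taxa) < 4:
                continue
            wS[g], wSVU[g], wU[g] = _score_tree_kernel(
                w, w2, side, dum, self.n_dummy,
                st.comp_lo, st.comp_hi, st.comp_is_compl, st.node_ptr)
        return ScoreParts(wS, wSVU, wU)

    def score(self) -> float:
        total = 0.0
        for st, w, w2, side, dum, _ in self._trees:
            if st.n_internal == 0 or len(st.leaf_taxa) < 4:
                continue
            ws, wsvu, wu = _score_tree_kernel(
                w, w2, side, dum, self.n_dummy,
                st.comp_lo, st.comp_hi, st.comp_is_compl, st.node_ptr)
            total += 2.0 * ws - wsvu + wu
        return total

    def score_of(self, bipartition: Bipartition) -> float:
        self.set_bipartition(bipartition)
        return self.score()

    def gain_from_current(self, item, current_score: float) -> float:
        """Score change of transferring ``item``, leaving state unchanged."""
        self._flip(item)
        s = self.score()
        self._flip(item)
        return s - current_score


def score_bipartition(bipartition: Bipartition, gene_trees,
                      weights: WeightAssignment) -> ScoreParts:
    """Score a candidate bipartition against all gene trees.

    Returns the per-gene-tree (wS, wSVU, wU) triples; the aggregate is
    ``ScoreParts.total``.
    """
    session = ScoringSession(gene_trees, weights)
    session.set_bipartition(bipartition)
    return session.score_parts()


def gain(bipartition: Bipartition, item, gene_trees,
         weights: WeightAssignment) -> float:
    """Exact score change of transferring ``item`` to the opposite side.

    Defined (and computed) as the difference of two full score evaluations;
    the move may not empty its source side.
    """
    moved = bipartition.move(item)  # raises if the move empties a side
    session = ScoringSession(gene_trees, weights)
    before = session.score_of(bipartition)
    after = session.score_of(moved)
    return after - before


def _single_tree_parts(tree, bipartition, weights):
    session = ScoringSession([tree], weights)
    session.set_bipartition(bipartition)
    parts = session.score_parts()
    return float(parts.wS[0]), float(parts.wSVU[0]), float(parts.wU[0])


def satisfied_weight(tree: UnrootedGeneTree, bipartition: Bipartition,
                     weights: WeightAssignment) -> float:
    """w(S(g)): total weight of satisfied resolved quartets in one gene tree."""
    return _single_tree_parts(tree, bipartition, weights)[0]


def total_sv_u_weight(tree: UnrootedGeneTree, bipartition: Bipartition,
                      weights: WeightAssignment) -> float:
    """w(S u V u U) = w(PA(g)) * w(PB(g)) for one gene tree."""
    return _single_tree_parts(tree, bipartition, weights)[1]


def unresolved_weight(tree: UnrootedGeneTree, bipartition: Bipartition,
                      weights: WeightAssignment) -> float:
    """w(U(g)): weight of two-per-side unresolved quartets (polytomy nodes)."""
    return _single_tree_parts(tree, bipartition, weights)[2]


def satisfied_weight_per_node(tree: UnrootedGeneTree, bipartition: Bipartition,
                              weights: WeightAssignment) -> dict[int, float]:
    """Per-anchor-node satisfied weights w(S(g, u)), keyed by internal node id.

    Pure-Python mirror of the kernel's per-node decomposition, computed from
    the components of the tree at each internal node; used to validate the
    claim that anchor assignment partitions the satisfied quartet set.
    """
    fa = bipartition.FA
    fb = bipartition.FB
    w = weights.float_weight
    out: dict[int, float] = {}
    for u in tree.internal_nodes():
        comps = _node_components(tree, u)
        # per-component A-sums, B-sums, per-dummy breakdowns
        stats = []
        for comp in comps:
            sa = sb = qb = 0.0
            sad: dict[int, float] = {}
            sbd: dict[int, float] = {}
            qbd: dict[int, float] = {}
            for tax in comp:
                if tax not in w:
                    continue
                d = weights.dummy_id_of(tax)
                if tax in fa:
                    sa += w[tax]
                    if d >= 0:
                        sad[d] = sad.get(d, 0.0) + w[tax]
                elif tax in fb:
                    sb += w[tax]
                    qb += w[tax] ** 2
                    if d >= 0:
                        sbd[d] = sbd.get(d, 0.0) + w[tax]
                        qbd[d] = qbd.get(d, 0.0) + w[tax] ** 2
            stats.append((sa, sb, qb, sad, sbd, qbd))
        total = 0.0
        nc = len(stats)
        for i in range(nc):
            for j in range(i + 1, nc):
                sa_i, _, _, sad_i, _, _ = stats[i]
                sa_j, _, _, sad_j, _, _ = stats[j]
                pa_ij = sa_i * sa_j
                for d, v in sad_i.items():
                    pa_ij -= v * sad_j.get(d, 0.0)
                if pa_ij == 0.0:
                    continue
                for k in range(nc):
                    if k in (i, j):
                        continue
                    _, sb_k, qb_k, _, sbd_k, qbd_k = stats[k]
                    pb_k = 0.5 * (sb_k * sb_k - qb_k)
                    for d, v in sbd_k.items():
                        pb_k -= 0.5 * (v * v - qbd_k[d])
                    total += pa_ij * pb_k
        out[u] = total
    return out


def _node_components(tree: UnrootedGeneTree, u: int):
    """Leaf-label sets of the components of the tree with node u removed."""
    comps = []
    for start in tree.adjacency[u]:
        seen = {u, start}
        stack = [start]
        labels = []
        while stack:
            v = stack.pop()
            if v in tree.leaf_labels:
                labels.append(tree.leaf_labels[v])
            for x in tree.adjacency[v]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        comps.append(labels)
    return comps


def score_parts_table(parts: ScoreParts) -> str:
    """Render per-gene-tree score parts as TSV (diagnostics)."""
    lines = ["gene\twS\twSVU\twU"]
    for g in range(len(parts.wS)):
        lines.append(f"{g}\t{parts.wS[g]:.12g}\t{parts.wSVU[g]:.12g}\t{parts.wU[g]:.12g}")
    lines.append(f"total\t{parts.total:.12g}")
    return "\n".join(lines)
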
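"""Synthetic inputs: Yule species trees, multispecies-coalescent gene trees,
and the RF/Wilcoxon evaluation harness.

The simulator is a minimal multispecies coalescent (MSC): one sampled
lineage per species, no gene duplication/loss or gene-tree estimation
error.  A pure-birth (Yule) species tree provides the model topology with
branch lengths in time units; a discordance scaler converts them to
coalescent units (branch of time length t has coalescent length t /
``ils_scale``, so larger scalers mean shorter coalescent branches and more
incomplete lineage sorting).  Optional per-gene leaf deletion produces
incomplete trees and random edge contraction produces polytomies.

The correctness anchor is the standard MSC rooted-triple identity: for an
internal branch of coalescent length t, the gene triple matches the
species triple with probability 1 - (2/3) e^{-t}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import Node, UnrootedGeneTree, robinson_foulds, rooted_to_unrooted


@dataclass
class SimulationConfig:
    """Study conditions for one simulated replicate set.

    ``ils_scale`` divides time-unit branch lengths into coalescent units;
    0.2 gives moderate discordance on 16-taxon Yule trees and 0.02 nearly
    none.  ``missing_fraction`` deletes each taxon from each gene tree
    independently; ``polytomy_prob`` contracts each internal gene-tree edge
    independently.
    """

    n_taxa: int = 16
    n_genes: int = 200
    birth_rate: float = 1.0
    ils_scale: float = 0.2
    missing_fraction: float = 0.0
    polytomy_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.missing_fraction, self.polytomy_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_taxa < 4:
            raise ValueError("need at least four taxa")


class _SpNode(Node):
    __slots__ = ("length",)

    def __init__(self, label=None, children=None, length=0.0):
        super().__init__(label, children)
        self.length = length


def simulate_species_tree(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> Node:
    """Yule (pure-birth) species tree with exponential waiting times.

    Returns a rooted binary tree whose nodes carry ``length`` attributes in
    time units; taxa are labeled T1..Tn.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_taxa
    rate = config.birth_rate
    # active lineages: (node, birth_time); grow until n tips, then cut at T
    root = _SpNode()
    active = [(root, 0.0)]
    now = 0.0
    while len(active) < n:
        m = len(active)
        now += rng.exponential(1.0 / (rate * m))
        i = int(rng.integers(m))
        node, born = active.pop(i)
        node.length = now - born
        kids = (_SpNode(), _SpNode())
        node.children = list(kids)
        active.append((kids[0], now))
        active.append((kids[1], now))
    now += rng.exponential(1.0 / (rate * n))  # stem below the next event
    order = rng.permutation(n)
    for j, (node, born) in enumerate(active):
        node.length = now - born
        node.label = f"T{order[j] + 1}"
    return root


def simulate_gene_trees(species_tree: Node, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> list[UnrootedGeneTree]:
    """Coalescent gene trees within the species tree (one lineage/species)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    out = []
    for g in range(config.n_genes):
        root_lineages = _coalesce_in(species_tree, config, rng)
        while len(root_lineages) > 1:  # above the species root: unbounded
            root_lineages = _coalesce_step(root_lineages, rng)
        gene_root = root_lineages[0]
        if config.polytomy_prob > 0.0:
            gene_root = _contract_edges(gene_root, config.polytomy_prob, rng)
        out.append(rooted_to_unrooted(gene_root, tree_index=g))
    return out


def _coalesce_in(v: Node, config: SimulationConfig,
                 rng: np.random.Generator) -> list[Node]:
    if v.is_leaf:
        if config.missing_fraction > 0.0 and rng.random() < config.missing_fraction:
            return []
        return [Node(v.label)]
    lineages: list[Node] = []
    for c in v.children:
        lineages.extend(_coalesce_in(c, config, rng))
    t_remaining = getattr(v, "length", 0.0) / config.ils_scale
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if wait > t_remaining:
            break
        t_remaining -= wait
        lineages = _coalesce_step(lineages, rng)
    return lineages


def _coalesce_step(lineages: list[Node], rng: np.random.Generator) -> list[Node]:
    k = len(lineages)
    i, j = rng.choice(k, size=2, replace=False)
    i, j = (int(i), int(j)) if i < j else (int(j), int(i))
    joined = Node(None, [lineages[i], lineages[j]])
    return [x for idx, x in enumerate(lineages) if idx not in (i, j)] + [joined]


def _contract_edges(root: Node, prob: float, rng: np.random.Generator) -> Node:
    """Contract each internal edge independently with probability ``prob``."""

    def rec(v: Node):
        new_children = []
        for c in v.children:
            rec(c)
            if not c.is_leaf and rng.random() < prob:
                new_children.extend(c.children)
            else:
                new_children.append(c)
        v.children = new_children

    rec(root)
    return root


def triple_match_probability(t: float) -> float:
    """MSC probability that a rooted triple matches the species triple."""
    return 1.0 - (2.0 / 3.0) * math.exp(-t)


# ---------------------------------------------------------------------------
# Randomized micro-instances (uniform random trees, dummy nestings,
# bipartitions) for exercising the scorer against the enumeration oracle
# ---------------------------------------------------------------------------


def random_binary_rooted(labels, rng: np.random.Generator) -> Node:
    """Uniform random rooted binary topology by random sequential joins."""
    nodes = [Node(l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(int(x) for x in rng.choice(len(nodes), 2, replace=False))
        joined = Node(None, [nodes[i], nodes[j]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [joined]
    return nodes[0]


def random_unrooted_tree(labels, rng: np.random.Generator,
                         polytomy_prob: float = 0.0) -> UnrootedGeneTree:
    """Random unrooted tree, optionally with contracted (polytomy) edges."""
    root = random_binary_rooted(labels, rng)
    if polytomy_prob > 0.0:
        root = _contract_edges(root, polytomy_prob, rng)
    return rooted_to_unrooted(root)


def random_scoring_instance(rng: np.random.Generator,
                            n_range=(4, 12), k_range=(1, 20),
                            missing_fraction: float = 0.4,
                            polytomy_prob: float = 0.3,
                            max_dummy_depth: int = 3):
    """One randomized scoring problem: gene trees, items, weights, bipartition.

    Taxa counts, tree counts, per-tree taxon subsets (at least 4 kept),
    polytomies (edge contraction), nested dummy structures (wrapping random
    item groups up to ``max_dummy_depth`` times) and the bipartition are all
    drawn from ``rng``.
    """
    from .dummy import leaf_weights, make_dummy
    from .scoring import Bipartition

    n = int(rng.integers(n_range[0], n_range[1] + 1))
    k = int(rng.integers(k_range[0], k_range[1] + 1))
    taxa = [f"t{i}" for i in range(n)]
    trees = []
    for g in range(k):
        keep = [t for t in taxa if rng.random() > missing_fraction]
        if len(keep) < 4:
            keep = [taxa[int(i)] for i in rng.choice(n, 4, replace=False)]
        trees.append(random_unrooted_tree(keep, rng, polytomy_prob))
    items = list(taxa)
    for _ in range(int(rng.integers(0, max_dummy_depth + 1))):
        if len(items) < 3:
            break
        m = int(rng.integers(2, min(5, len(items))))
        idx = set(int(i) for i in rng.choice(len(items), m, replace=False))
        group = [items[i] for i in idx]
        items = [it for i, it in enumerate(items) if i not in idx]
        items.append(make_dummy(group))
    weights = leaf_weights(items)
    na = int(rng.integers(1, len(items)))
    order = [int(i) for i in rng.permutation(len(items))]
    bip = Bipartition(tuple(items[i] for i in order[:na]),
                      tuple(items[i] for i in order[na:]))
    return trees, tuple(items), weights, bip


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------


def rf_table(estimates, truths) -> pd.DataFrame:
    """Per-replicate normalized RF distances between estimates and truths."""
    if len(estimates) != len(truths):
        raise ValueError("replicate counts differ")
    rows = [{"replicate": i, "rf": robinson_foulds(est, tru)}
            for i, (est, tru) in enumerate(zip(estimates, truths))]
    return pd.DataFrame(rows)


def compare_methods(rf_a, rf_b, alpha: float = 0.05) -> dict:
    """Two-sided paired Wilcoxon signed-rank test between two RF vectors.

    When every paired difference is zero the test statistic is undefined;
    this is reported as ``p = nan`` with ``defined = False``.
    """
    rf_a = np.asarray(rf_a, float)
    rf_b = np.asarray(rf_b, float)
    if rf_a.shape != rf_b.shape:
        raise ValueError("RF vectors have different lengths")
    diffs = rf_a - rf_b
    if np.all(diffs == 0):
        return {"statistic": float("nan"), "p_value": float("nan"),
                "significant": False, "defined": False}
    res = stats.wilcoxon(rf_a, rf_b, alternative="two-sided")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "significant": bool(res.pvalue < alpha), "defined": True}


def evaluate(estimates_a, truths, estimates_b=None, alpha: float = 0.05):
    """RF table for one method, optionally with a paired Wilcoxon test
    against a second method's estimates on the same replicates."""
    table = rf_table(estimates_a, truths).rename(columns={"rf": "rf_a"})
    test = None
    if estimates_b is not None:
        table_b = rf_table(estimates_b, truths)
        table["rf_b"] = table_b["rf"]
        test = compare_methods(table["rf_a"], table["rf_b"], alpha=alpha)
    return table, test
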
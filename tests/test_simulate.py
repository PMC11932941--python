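"""Yule + coalescent simulator and the evaluation harness."""

import math

import numpy as np
import pytest
from scipy import stats

from wqfmtree.simulate import (SimulationConfig, compare_methods, evaluate,
                               rf_table, simulate_gene_trees,
                               simulate_species_tree, triple_match_probability)
from wqfmtree.treeio import Node, robinson_foulds, rooted_to_unrooted


class _LenNode(Node):
    __slots__ = ("length",)

    def __init__(self, label=None, children=None, length=0.0):
        super().__init__(label, children)
        self.length = length


class TestSpeciesTree:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_taxa=10, seed=42)
        t1 = simulate_species_tree(cfg)
        t2 = simulate_species_tree(cfg)
        from wqfmtree.treeio import write_newick

        assert write_newick(t1) == write_newick(t2)

    @pytest.mark.parametrize("n", [4, 7, 16])
    def test_leaf_count(self, n):
        t = simulate_species_tree(SimulationConfig(n_taxa=n, seed=1))
        assert len(t.leaf_labels()) == n

    def test_all_unrooted_five_taxon_topologies_reachable(self):
        seen = set()
        rng = np.random.default_rng(2024)
        cfg = SimulationConfig(n_taxa=5, seed=0)
        for _ in range(1000):
            t = simulate_species_tree(cfg, rng)
            u = rooted_to_unrooted(t)
            seen.add(frozenset(u.nontrivial_bipartitions()))
        assert len(seen) == 15  # all labeled unrooted binary shapes on 5 taxa

    def test_branch_lengths_positive(self):
        t = simulate_species_tree(SimulationConfig(n_taxa=8, seed=3))
        stack = [t]
        while stack:
            v = stack.pop()
            assert v.length >= 0
            stack.extend(v.children)


class TestGeneTrees:
    def test_no_ils_limit_recovers_species_tree(self):
        cfg = SimulationConfig(n_taxa=10, n_genes=5, ils_scale=1e-4, seed=7)
        rng = np.random.default_rng(7)
        sp = simulate_species_tree(cfg, rng)
        genes = simulate_gene_trees(sp, cfg, rng)
        tru = rooted_to_unrooted(sp)
        for g in genes:
            assert robinson_foulds(g, tru) == 0.0

    def test_rooted_triple_probability_closed_form(self):
        # species tree (((A,B):t,C):long,D): the A-B-C triple resolves like
        # a rooted triple with internal branch t, and a distant outgroup D
        # makes the resolution readable from the unrooted quartet topology
        from wqfmtree.oracle import induced_topology

        t = 0.7
        ab = _LenNode(None, [_LenNode("A", length=1.0), _LenNode("B", length=1.0)],
                      length=t)
        abc = _LenNode(None, [ab, _LenNode("C", length=1.0 + t)], length=25.0)
        sp = _LenNode(None, [abc, _LenNode("D", length=26.0 + t)], length=0.0)
        cfg = SimulationConfig(n_taxa=4, n_genes=10000, ils_scale=1.0, seed=5)
        rng = np.random.default_rng(5)
        genes = simulate_gene_trees(sp, cfg, rng)
        matches = 0
        for g in genes:
            topo = induced_topology(g, ("A", "B", "C", "D"))
            matches += topo is not None and frozenset(
                ("A", "B")) in {frozenset(p) for p in topo}
        p_hat = matches / len(genes)
        p = triple_match_probability(t)
        se = math.sqrt(p * (1 - p) / len(genes))
        assert abs(p_hat - p) <= 3 * se

    def test_missing_fraction_thins_leaves(self):
        cfg = SimulationConfig(n_taxa=20, n_genes=300, ils_scale=0.2,
                               missing_fraction=0.3, seed=11)
        rng = np.random.default_rng(11)
        sp = simulate_species_tree(cfg, rng)
        genes = simulate_gene_trees(sp, cfg, rng)
        mean_leaves = np.mean([g.n_leaves for g in genes])
        expected = 0.7 * 20
        se = math.sqrt(20 * 0.3 * 0.7 / len(genes))
        assert abs(mean_leaves - expected) <= 4 * se

    def test_polytomy_contraction_produces_polytomies(self):
        cfg = SimulationConfig(n_taxa=12, n_genes=50, ils_scale=0.2,
                               polytomy_prob=0.4, seed=13)
        rng = np.random.default_rng(13)
        sp = simulate_species_tree(cfg, rng)
        genes = simulate_gene_trees(sp, cfg, rng)
        assert any(g.has_polytomy() for g in genes)

    def test_seeded_determinism_end_to_end(self):
        from wqfmtree.treeio import write_newick

        cfg = SimulationConfig(n_taxa=8, n_genes=10, ils_scale=0.3, seed=21)

        def render():
            rng = np.random.default_rng(21)
            sp = simulate_species_tree(cfg, rng)
            genes = simulate_gene_trees(sp, cfg, rng)
            return [write_newick(g.to_rooted()) for g in genes]

        assert render() == render()


class TestEvaluation:
    def test_rf_of_truth_against_itself_is_zero(self, random_tree_factory):
        truths = [random_tree_factory(8, seed=s) for s in range(4)]
        table = rf_table(truths, truths)
        assert (table["rf"] == 0).all()

    def test_length_mismatch_rejected(self, random_tree_factory):
        t = random_tree_factory(8, seed=0)
        with pytest.raises(ValueError):
            rf_table([t], [t, t])

    def test_identical_vectors_reported_undefined(self):
        res = compare_methods([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["defined"] is False
        assert not res["significant"]

    def test_signed_rank_statistic_matches_manual_computation(self):
        a = [0.10, 0.20, 0.30, 0.15, 0.25, 0.05]
        b = [0.20, 0.10, 0.35, 0.20, 0.20, 0.10]
        res = compare_methods(a, b)
        diffs = np.array(a) - np.array(b)
        ranks = stats.rankdata(np.abs(diffs))
        w_plus = ranks[diffs > 0].sum()
        w_minus = ranks[diffs < 0].sum()
        assert res["statistic"] == pytest.approx(min(w_plus, w_minus))
        assert 0 < res["p_value"] <= 1

    def test_evaluate_two_methods(self, random_tree_factory):
        truths = [random_tree_factory(8, seed=s) for s in range(6)]
        ests = [random_tree_factory(8, seed=100 + s) for s in range(6)]
        table, test = evaluate(ests, truths, estimates_b=truths)
        assert set(table.columns) >= {"replicate", "rf_a", "rf_b"}
        assert (table["rf_b"] == 0).all()
        assert test is not None
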
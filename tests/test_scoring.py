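"""The quartet-free scorer against definitions and the enumeration oracle."""

import numpy as np
import pytest

from wqfmtree.dummy import leaf_weights, make_dummy
from wqfmtree.oracle import oracle_score, oracle_score_tree
from wqfmtree.scoring import (Bipartition, QuartetClass, classify_quartet,
                              gain, satisfied_weight, score_bipartition,
                              total_sv_u_weight, unresolved_weight)
from wqfmtree.simulate import random_scoring_instance, random_unrooted_tree
from wqfmtree.treeio import parse_newick

QUARTET = parse_newick("((a,b),(c,d));")
STAR = parse_newick("(a,b,c,d);")
ALL_REAL = leaf_weights(("a", "b", "c", "d"))


def unit_weights(labels):
    return leaf_weights(tuple(labels))


class TestClassifyQuartet:
    TOPO = (("a", "b"), ("c", "d"))

    def classify(self, fa, topology=TOPO, dummy_ids=None):
        dummy_ids = dummy_ids or {}
        return classify_quartet(("a", "b", "c", "d"), topology,
                                frozenset(fa), lambda t: dummy_ids.get(t, -1))

    def test_pairs_aligned_with_sides_satisfied(self):
        assert self.classify("ab") is QuartetClass.SATISFIED
        assert self.classify("cd") is QuartetClass.SATISFIED

    def test_three_on_one_side_deferred(self):
        assert self.classify("abc") is QuartetClass.DEFERRED
        assert self.classify("d") is QuartetClass.DEFERRED

    def test_mispaired_violated(self):
        assert self.classify("ac") is QuartetClass.VIOLATED

    def test_shared_dummy_excluded(self):
        assert self.classify("ab", dummy_ids={"a": 7, "c": 7}) is QuartetClass.EXCLUDED

    def test_unresolved_two_per_side_counts_toward_u(self):
        assert self.classify("ab", topology=None) is QuartetClass.UNRESOLVED
        assert self.classify("abc", topology=None) is QuartetClass.DEFERRED


class TestWeightComponents:
    def test_single_quartet_satisfied_weight(self):
        bip = Bipartition(("a", "b"), ("c", "d"))
        assert satisfied_weight(QUARTET[0], bip, ALL_REAL) == pytest.approx(1.0)

    def test_no_pair_on_side_a_gives_zero(self):
        bip = Bipartition(("a",), ("b", "c", "d"))
        assert satisfied_weight(QUARTET[0], bip, ALL_REAL) == 0.0

    def test_total_weight_is_pair_product(self):
        bip = Bipartition(("a", "b"), ("c", "d"))
        assert total_sv_u_weight(QUARTET[0], bip, ALL_REAL) == pytest.approx(1.0)

    def test_side_fully_under_one_dummy_excludes_all_pairs(self):
        d = make_dummy(["a", "b"])
        w = leaf_weights((d, "c", "d"))
        bip = Bipartition((d,), ("c", "d"))
        assert total_sv_u_weight(QUARTET[0], bip, w) == 0.0

    def test_binary_tree_has_no_unresolved_weight(self):
        bip = Bipartition(("a", "b"), ("c", "d"))
        assert unresolved_weight(QUARTET[0], bip, ALL_REAL) == 0.0

    def test_star_quartet_unresolved_weight_one(self):
        bip = Bipartition(("a", "b"), ("c", "d"))
        assert unresolved_weight(STAR[0], bip, ALL_REAL) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_high_degree_polytomies_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(8)]
        tree = random_unrooted_tree(labels, r, polytomy_prob=0.6)
        w = unit_weights(labels)
        bip = Bipartition(tuple(labels[:4]), tuple(labels[4:]))
        o = oracle_score_tree(tree, bip, w)
        assert unresolved_weight(tree, bip, w) == pytest.approx(float(o.wU), abs=1e-12)
        assert satisfied_weight(tree, bip, w) == pytest.approx(float(o.wS), abs=1e-12)


class TestScoreBipartition:
    def test_satisfied_quartet_scores_one(self):
        parts = score_bipartition(Bipartition(("a", "b"), ("c", "d")),
                                  QUARTET, ALL_REAL)
        assert parts.total == pytest.approx(1.0)

    def test_violated_quartet_scores_minus_one(self):
        parts = score_bipartition(Bipartition(("a", "c"), ("b", "d")),
                                  QUARTET, ALL_REAL)
        assert parts.total == pytest.approx(-1.0)

    def test_singleton_side_scores_zero(self):
        parts = score_bipartition(Bipartition(("a",), ("b", "c", "d")),
                                  QUARTET, ALL_REAL)
        assert parts.total == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_orientation_symmetry(self, seed):
        rng = np.random.default_rng(1000 + seed)
        trees, items, w, bip = random_scoring_instance(rng)
        forward = score_bipartition(bip, trees, w).total
        backward = score_bipartition(bip.swap(), trees, w).total
        assert forward == pytest.approx(backward, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_unit_weight_scores_are_satisfied_minus_violated_counts(self, seed):
        rng = np.random.default_rng(2000 + seed)
        trees, items, w, bip = random_scoring_instance(rng, max_dummy_depth=0)
        parts = score_bipartition(bip, trees, w)
        per_tree, total = oracle_score(bip, trees, w)
        n_sat = sum(o.n_satisfied for o in per_tree)
        n_vio = sum(o.n_violated for o in per_tree)
        assert parts.total == pytest.approx(n_sat - n_vio, abs=1e-9)
        assert round(parts.total) == pytest.approx(parts.total, abs=1e-9)

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(3000 + seed)
        trees, items, w, bip = random_scoring_instance(rng, k_range=(1, 8))
        parts = score_bipartition(bip, trees, w)
        per_tree, total = oracle_score(bip, trees, w)
        assert np.sum(parts.wS) == pytest.approx(
            float(sum(o.wS for o in per_tree)), abs=1e-9)
        assert np.sum(parts.wSVU) == pytest.approx(
            float(sum(o.wSVU for o in per_tree)), abs=1e-9)
        assert np.sum(parts.wU) == pytest.approx(
            float(sum(o.wU for o in per_tree)), abs=1e-9)
        assert parts.total == pytest.approx(float(total), abs=1e-9)
        # violated weight recovered from the decomposition is non-negative
        w_v = np.sum(parts.wSVU) - np.sum(parts.wS) - np.sum(parts.wU)
        assert w_v == pytest.approx(float(sum(o.wV for o in per_tree)), abs=1e-9)
        assert w_v >= -1e-9


class TestGain:
    def test_move_to_deferred_loses_one(self):
        bip = Bipartition(("a", "b"), ("c", "d"))
        assert gain(bip, "c", QUARTET, ALL_REAL) == pytest.approx(-1.0)

    def test_move_and_move_back_cancel(self):
        bip = Bipartition(("a", "b"), ("c", "d"))
        g1 = gain(bip, "c", QUARTET, ALL_REAL)
        g2 = gain(bip.move("c"), "c", QUARTET, ALL_REAL)
        assert g1 + g2 == pytest.approx(0.0, abs=1e-12)

    def test_emptying_a_side_rejected(self):
        bip = Bipartition(("a",), ("b", "c", "d"))
        with pytest.raises(ValueError):
            gain(bip, "a", QUARTET, ALL_REAL)

    @pytest.mark.parametrize("seed", range(15))
    def test_equals_score_difference_for_every_legal_move(self, seed):
        rng = np.random.default_rng(4000 + seed)
        trees, items, w, bip = random_scoring_instance(rng, k_range=(1, 6))
        before = score_bipartition(bip, trees, w).total
        for it in items:
            side = bip.A if it in bip.A else bip.B
            if len(side) < 2:
                continue
            after = score_bipartition(bip.move(it), trees, w).total
            assert gain(bip, it, trees, w) == pytest.approx(
                after - before, abs=1e-9)
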
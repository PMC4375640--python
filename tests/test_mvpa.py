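import logging

import numpy as np
import pytest

from connmvpa.mvpa import (
    ConsensusResult,
    LabeledDataset,
    SelectionRule,
    SVMParams,
    consensus_features,
    region_weights,
    train_classifier,
    ttest_select,
)
from connmvpa.network import FeatureIndexMap


class TestTTestSelect:
    def test_hand_computed_example(self):
        # groups [1,2,3] vs [4,5,6]: pooled sd = 1, se = sqrt(2/3),
        # t = -3/se = -3.674, p ~ 0.0214 on 4 df
        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        sel, t, p = ttest_select(x, y, SelectionRule(alpha=0.05))
        assert t[0] == pytest.approx(-3.674, abs=1e-3)
        assert p[0] == pytest.approx(0.0214, abs=1e-3)
        assert list(sel) == [0]

    def test_constant_equal_feature_not_selected(self, rng):
        x = np.column_stack([np.ones(10), rng.normal(0, 1, 10) + np.r_[np.zeros(5), 5 * np.ones(5)]])
        y = np.array(["a"] * 5 + ["b"] * 5)
        sel, t, p = ttest_select(x, y, SelectionRule())
        assert t[0] == 0.0 and p[0] == 1.0
        assert 0 not in sel and 1 in sel

    def test_constant_but_split_feature_maximally_significant(self):
        x = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        sel, t, p = ttest_select(x, y, SelectionRule())
        assert p[0] == 0.0 and np.isinf(t[0]) and t[0] < 0
        assert 0 in sel

    def test_null_selection_rate_matches_alpha(self):
        # identical group distributions: expected selected fraction ~ alpha
        rng = np.random.default_rng(42)
        fractions = []
        y = np.array(["a"] * 10 + ["b"] * 10)
        for _ in range(100):
            x = rng.normal(size=(20, 200))
            _, _, p = ttest_select(x, y, SelectionRule())
            fractions.append((p < 0.05).mean())
        mean = np.mean(fractions)
        # binomial band for 100*200 draws (correlated only weakly)
        assert abs(mean - 0.05) < 0.01

    def test_fallback_when_nothing_passes(self, caplog):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 6))
        y = np.array(["a"] * 6 + ["b"] * 6)
        with caplog.at_level(logging.WARNING, logger="connmvpa.mvpa"):
            sel, _, p = ttest_select(x, y, SelectionRule(alpha=1e-9, fallback_k=4))
        if (p < 1e-9).sum() == 0:
            assert sel.size == 4
            assert "falling back" in caplog.text

    def test_errors(self):
        with pytest.raises(ValueError, match="2 classes"):
            ttest_select(np.zeros((4, 2)), np.array(["a"] * 4), SelectionRule())
        with pytest.raises(ValueError, match=">= 2 subjects"):
            ttest_select(np.zeros((3, 2)), np.array(["a", "a", "b"]),
                         SelectionRule())

    def test_welch_variant_differs_under_unequal_variances(self, rng):
        # unequal group sizes and variances: Welch and Student disagree
        x = rng.normal(size=(12, 5))
        x[:8] *= 4
        y = np.array(["a"] * 8 + ["b"] * 4)
        _, t_w, p_w = ttest_select(x, y, SelectionRule(variant="welch"))
        _, t_p, p_p = ttest_select(x, y, SelectionRule(variant="pooled"))
        assert not np.allclose(t_w, t_p)
        assert not np.allclose(p_w, p_p)


class TestTrainClassifier:
    def test_separable_clusters(self, rng):
        z = np.r_[rng.normal(0, 1, (10, 2)), rng.normal(20, 1, (10, 2))]
        y = np.array([0] * 10 + [1] * 10)
        clf = train_classifier(z, y)
        assert clf.score(z, y) == 1.0

    def test_label_flip_negates_scores(self, rng):
        z = np.r_[rng.normal(0, 1, (8, 2)), rng.normal(4, 1, (8, 2))]
        y = np.array([0] * 8 + [1] * 8)
        grid = rng.normal(2, 2, (20, 2))
        s1 = train_classifier(z, y).decision_function(grid)
        s2 = train_classifier(z, 1 - y).decision_function(grid)
        # SMO converges to tolerance, so symmetry holds approximately
        assert np.allclose(s1, -s2, atol=1e-3)

    def test_duplicated_training_set_same_predictions(self, rng):
        z = np.r_[rng.normal(0, 0.5, (8, 2)), rng.normal(10, 0.5, (8, 2))]
        y = np.array([0] * 8 + [1] * 8)
        grid = rng.uniform(-2, 12, (50, 2))
        p1 = train_classifier(z, y).predict(grid)
        p2 = train_classifier(np.r_[z, z], np.r_[y, y]).predict(grid)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(np.zeros((4, 2)), np.zeros(4))

    def test_default_gamma_is_one_over_dim(self, rng):
        z = rng.normal(size=(10, 4))
        y = np.array([0] * 5 + [1] * 5)
        clf = train_classifier(z, y, SVMParams())
        assert clf._gamma == pytest.approx(0.25)


class TestConsensus:
    def test_intersection(self):
        folds = [np.array([1, 2, 3]), np.array([2, 3, 4]), np.array([2, 3])]
        res = consensus_features(folds)
        assert list(res.feature_ids) == [2, 3]

    def test_identical_folds(self):
        folds = [np.array([5, 9])] * 4
        assert list(consensus_features(folds).feature_ids) == [5, 9]

    def test_disjoint_fold_gives_empty(self):
        res = consensus_features([np.array([1, 2]), np.array([3])])
        assert res.n_features == 0

    def test_direction_from_full_data(self):
        x = np.array([[1.0, 5.0]] * 4 + [[3.0, 2.0]] * 4)
        y = np.array(["a"] * 4 + ["b"] * 4)
        folds = [np.array([0, 1])] * 3
        t_vals = [np.array([-2.0, 3.0])] * 3
        res = consensus_features(folds, t_vals, x, y)
        assert list(res.direction) == [-1, 1]  # a lower at 0, higher at 1
        assert np.allclose(res.mean_t, [-2.0, 3.0])


class TestRegionWeights:
    def make_consensus(self, ids, t):
        ids = np.asarray(ids)
        return ConsensusResult(ids, np.asarray(t, dtype=float),
                               np.ones(len(ids), dtype=int))

    def test_empty_consensus(self):
        m = FeatureIndexMap(6)
        assert (region_weights(self.make_consensus([], []), m) == 0).all()

    def test_single_feature(self):
        m = FeatureIndexMap(5)
        fid = m.pair_to_index(1, 3)
        w = region_weights(self.make_consensus([fid], [2.5]), m)
        assert w[1] == w[3] == 1.0
        assert w[[0, 2, 4]].sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_incidence(self, seed):
        rng = np.random.default_rng(seed)
        m = FeatureIndexMap(9)
        ids = rng.choice(m.n_features, size=8, replace=False)
        t = rng.normal(size=8) * 3
        w = region_weights(self.make_consensus(ids, t), m)
        brute = np.zeros(9)
        for fid, tv in zip(ids, t):
            v, u = m.index_to_pair(int(fid))
            brute[v] += abs(tv)
            brute[u] += abs(tv)
        brute /= brute.max()
        assert np.allclose(w, brute)

    def test_permutation_equivariance(self, rng):
        # relabeling regions permutes the weight vector accordingly
        m = FeatureIndexMap(7)
        ids = rng.choice(m.n_features, size=6, replace=False)
        t = rng.normal(size=6)
        w = region_weights(self.make_consensus(ids, t), m)
        perm = rng.permutation(7)
        perm_ids = []
        for fid in ids:
            v, u = m.index_to_pair(int(fid))
            pv, pu = sorted((perm[v], perm[u]))
            perm_ids.append(m.pair_to_index(pv, pu))
        w_perm = region_weights(self.make_consensus(perm_ids, t), m)
        assert np.allclose(w_perm[perm], w)


class TestLabeledDataset:
    def test_feature_count_validated(self, rng):
        m = FeatureIndexMap(4)
        with pytest.raises(ValueError, match="does not match"):
            LabeledDataset(rng.random((4, 5)), np.array(["a", "a", "b", "b"]), m)

    def test_small_group_rejected(self, rng):
        m = FeatureIndexMap(4)
        with pytest.raises(ValueError, match="< 2 subjects"):
            LabeledDataset(rng.random((3, 6)), np.array(["a", "a", "b"]), m)

    def test_subset(self, three_group_study):
        ds = three_group_study.dataset
        sub = ds.subset(["left", "control"])
        assert set(sub.y) == {"left", "control"}
        assert sub.n_subjects == 22
        with pytest.raises(ValueError, match="not in dataset"):
            ds.subset(["left", "ghost"])
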
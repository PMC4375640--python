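import numpy as np
import pytest

from connmvpa import SyntheticSpec, generate_dataset
from connmvpa.evaluation import (
    CVScheme,
    PipelineConfig,
    metrics,
    permutation_test,
    roc_points,
    run_cv,
    three_way_cv,
    vote,
)


class TestMetrics:
    def test_printed_group_size_arithmetic(self):
        # 21 of 22 positives and 19 of 21 negatives correct:
        # SS = 95.5%, SC = 90.5%, GR = 40/43 = 93.0%
        truth = np.array(["p"] * 22 + ["c"] * 21)
        pred = truth.copy()
        pred[0] = "c"            # one patient missed
        pred[22:24] = "p"        # two controls missed
        gr, ss, sc = metrics(pred, truth, positive_class="p")
        assert round(100 * ss, 1) == 95.5
        assert round(100 * sc, 1) == 90.5
        assert round(100 * gr, 1) == 93.0

    def test_all_correct_and_one_sided_failures(self):
        truth = np.array([1, 1, 0, 0])
        gr, ss, sc = metrics(truth, truth, 1)
        assert (gr, ss, sc) == (1.0, 1.0, 1.0)
        flipped_pos = np.array([0, 0, 0, 0])
        gr, ss, sc = metrics(flipped_pos, truth, 1)
        assert (ss, sc) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_counting_identity(self, seed):
        # GR*N = SS*N_pos + SC*N_neg whenever the two classes partition N
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, 30)
        truth[:2] = [0, 1]
        pred = rng.integers(0, 2, 30)
        gr, ss, sc = metrics(pred, truth, 1)
        n_pos, n_neg = (truth == 1).sum(), (truth == 0).sum()
        assert gr * 30 == pytest.approx(ss * n_pos + sc * n_neg)
        for v in (gr * 30, ss * n_pos, sc * n_neg):
            assert v == pytest.approx(round(v))

    def test_errors(self):
        with pytest.raises(ValueError):
            metrics(np.array([]), np.array([]), 1)
        with pytest.raises(ValueError, match="absent"):
            metrics(np.array([0, 0]), np.array([0, 0]), 1)


class TestRunCV:
    def test_loocv_fold_count_and_accuracy(self, tiny_study):
        ds = tiny_study.dataset
        res = run_cv(ds.x, ds.y, positive_class="patient")
        assert res.n_folds == ds.n_subjects
        assert res.gr >= 0.85  # strong planted effects are separable
        assert len(res.fold_selections) == res.n_folds

    def test_perfectly_separating_feature(self):
        # one feature splits the classes with a wide margin -> GR = 1
        spec = SyntheticSpec(n_regions=8, group_sizes={"a": 6, "b": 6},
                             n_planted=1, delta=8.0, sigma_subj=0.02,
                             density=0.8, seed=2)
        study = generate_dataset(spec)
        res = run_cv(study.dataset.x, study.dataset.y)
        assert res.gr == 1.0

    def test_confusion_counts_consistent(self, tiny_study):
        ds = tiny_study.dataset
        res = run_cv(ds.x, ds.y, positive_class="patient")
        c = res.confusion
        assert c["tp"] + c["fn"] == 10 and c["tn"] + c["fp"] == 10
        assert res.gr == pytest.approx((c["tp"] + c["tn"]) / 20)

    def test_consensus_subset_of_every_fold(self, tiny_study):
        from connmvpa.mvpa import consensus_features

        ds = tiny_study.dataset
        res = run_cv(ds.x, ds.y)
        cons = consensus_features(res.fold_selections)
        for sel in res.fold_selections:
            assert set(cons.feature_ids) <= set(sel)

    def test_no_leakage_from_test_subject(self, tiny_study):
        # corrupting a held-out subject's features must not change what the
        # fold trained on: fold selections are identical
        ds = tiny_study.dataset
        base = run_cv(ds.x, ds.y)
        x2 = ds.x.copy()
        x2[0] = np.max(ds.x) * 50  # absurd test-subject values
        mod = run_cv(x2, ds.y)
        # subject 0 is the held-out subject of fold 0 under LOOCV
        assert np.array_equal(base.fold_selections[0], mod.fold_selections[0])

    def test_feature_mask_restricts_selection(self, tiny_study):
        ds = tiny_study.dataset
        mask = np.ones(ds.x.shape[1], dtype=bool)
        blocked = ds.x.std(axis=0).argmax()
        mask[blocked] = False
        res = run_cv(ds.x, ds.y, feature_mask=mask)
        for sel in res.fold_selections:
            assert blocked not in sel

    def test_kfold_runs(self, tiny_study):
        ds = tiny_study.dataset
        res = run_cv(ds.x, ds.y, scheme=CVScheme("kfold", k=4))
        assert res.n_folds == 4

    def test_three_classes_rejected(self, three_group_study):
        ds = three_group_study.dataset
        with pytest.raises(ValueError, match="2 classes"):
            run_cv(ds.x, ds.y)


class TestPermutationTest:
    def test_extreme_observed_gr(self, tiny_study):
        ds = tiny_study.dataset
        res = permutation_test(ds.x, ds.y, n_perm=10, seed=0,
                               observed_gr=2.0)
        assert res.p_value == 0.0
        res = permutation_test(ds.x, ds.y, n_perm=10, seed=0,
                               observed_gr=-1.0)
        assert res.p_value == 1.0

    def test_seed_reproducibility_serial_vs_parallel(self, tiny_study):
        ds = tiny_study.dataset
        kw = dict(n_perm=6, seed=3, observed_gr=0.9)
        serial = permutation_test(ds.x, ds.y, **kw, n_jobs=1)
        parallel = permutation_test(ds.x, ds.y, **kw, n_jobs=2)
        assert np.array_equal(serial.null_gr, parallel.null_gr)
        assert serial.p_value == parallel.p_value

    def test_invariant_to_class_relabeling(self, tiny_study):
        ds = tiny_study.dataset
        relabeled = np.where(ds.y == "patient", "zzz", "aaa")
        a = permutation_test(ds.x, ds.y, n_perm=8, seed=1, observed_gr=0.5)
        b = permutation_test(ds.x, relabeled, n_perm=8, seed=1, observed_gr=0.5)
        assert np.array_equal(a.null_gr, b.null_gr)

    def test_add_one_rule(self, tiny_study):
        ds = tiny_study.dataset
        res = permutation_test(ds.x, ds.y, n_perm=5, seed=0,
                               observed_gr=2.0, add_one=True)
        assert res.p_value == pytest.approx(1 / 6)

    def test_invalid_n_perm(self, tiny_study):
        ds = tiny_study.dataset
        with pytest.raises(ValueError):
            permutation_test(ds.x, ds.y, n_perm=0)


class TestROC:
    def test_perfect_and_reversed_ranking(self):
        truth = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.0])
        assert roc_points(scores, truth, 1)[2] == 1.0
        assert roc_points(-scores, truth, 1)[2] == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 2000)
        scores = rng.normal(size=2000)
        assert roc_points(scores, truth, 1)[2] == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points(np.array([1.0, 2.0]), np.array([1, 1]), 1)


class TestThreeWay:
    def test_vote_majority(self):
        classes = np.array(["a", "b", "c"])
        assert vote(["a", "a", "b"], [0.5, 0.7, 0.1], classes) == "a"

    def test_vote_tie_broken_by_score_then_index(self):
        classes = np.array(["a", "b", "c"])
        assert vote(["a", "b", "c"], [0.9, 0.2, 0.1], classes) == "a"
        assert vote(["a", "b", "c"], [0.1, 0.9, 0.2], classes) == "b"
        # all-equal scores: lowest class index wins
        assert vote(["a", "b", "c"], [0.3, 0.3, 0.3], classes) == "a"

    def test_separated_three_groups(self, three_group_study):
        ds = three_group_study.dataset
        res = three_way_cv(ds.x, ds.y)
        assert res.total_accuracy >= 0.9
        assert set(res.per_class_accuracy) == {"left", "right", "control"}
        total = sum(res.per_class_accuracy[c] * (ds.y == c).sum()
                    for c in res.classes)
        assert res.total_accuracy == pytest.approx(total / ds.n_subjects)

    def test_two_classes_rejected(self, tiny_study):
        ds = tiny_study.dataset
        with pytest.raises(ValueError, match="3 classes"):
            three_way_cv(ds.x, ds.y)
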
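"""The fold engine: partitioning, metrics, ROC, weights, leakage."""

import numpy as np
import pytest
from scipy import stats as sps

import mvpkit
from mvpkit import crossval, synthetic
from mvpkit.crossval import ConfusionCounts
from mvpkit.data_io import DataError, FoldAssignment, LabelVector


class TestRandomFolds:
    def test_even_division(self):
        y = LabelVector("classification", np.r_[np.ones(20), -np.ones(20)])
        folds = mvpkit.random_folds(40, 10, y, seed=0)
        sizes = [len(folds.test_indices(k)) for k in range(1, 11)]
        assert sizes == [4] * 10

    def test_leave_one_pair_out_stratification(self):
        y = LabelVector("classification", np.r_[np.ones(20), -np.ones(20)])
        folds = mvpkit.random_folds(40, 20, y, seed=1)
        for k in range(1, 21):
            te = folds.test_indices(k)
            assert len(te) == 2
            assert set(y.values[te]) == {-1.0, 1.0}

    def test_uneven_sizes_differ_by_at_most_one(self):
        folds = mvpkit.random_folds(10, 4, None, seed=2)
        sizes = sorted(len(folds.test_indices(k)) for k in range(1, 5))
        assert sizes == [2, 2, 3, 3]

    def test_stratified_uneven_sizes(self):
        y = LabelVector("classification", np.r_[np.ones(5), -np.ones(5)])
        folds = mvpkit.random_folds(10, 4, y, seed=3)
        sizes = sorted(len(folds.test_indices(k)) for k in range(1, 5))
        assert sizes == [2, 2, 3, 3]
        for k in range(1, 5):
            counts = [np.sum(y.values[folds.test_indices(k)] == c)
                      for c in (-1, 1)]
            assert abs(counts[0] - counts[1]) <= 1

    def test_deterministic_given_seed(self):
        a = mvpkit.random_folds(30, 5, None, seed=9)
        b = mvpkit.random_folds(30, 5, None, seed=9)
        np.testing.assert_array_equal(a.fold_of_sample, b.fold_of_sample)

    def test_too_many_folds_rejected(self):
        with pytest.raises(DataError):
            mvpkit.random_folds(5, 6, None)


class TestConfusionMetrics:
    def test_worked_example_85_95_75(self):
        """TP=19, FN=1, TN=15, FP=5 at n=20+20."""
        m = mvpkit.confusion_metrics(ConfusionCounts(TP=19, TN=15, FP=5, FN=1))
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.95)
        assert m["specificity"] == pytest.approx(0.75)

    def test_all_correct(self):
        m = mvpkit.confusion_metrics(ConfusionCounts(10, 10, 0, 0))
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1, 1, 1)

    def test_all_wrong(self):
        m = mvpkit.confusion_metrics(ConfusionCounts(TP=0, TN=0, FP=10, FN=10))
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (0, 0, 0)

    def test_undefined_metric_is_none_not_zero(self):
        m = mvpkit.confusion_metrics(ConfusionCounts(TP=0, TN=5, FP=5, FN=0))
        assert m["sensitivity"] is None and m["specificity"] is not None


class TestRunCV:
    def test_separable_volumes_reach_perfect_accuracy(self, separable_dataset,
                                                      svc_pipeline):
        fm, labels, folds, _ = separable_dataset
        result = mvpkit.run_cv(fm, labels, folds, svc_pipeline, seed=0)
        assert result.statistic == 1.0

    def test_partition_each_sample_predicted_once(self, separable_dataset,
                                                  svc_pipeline):
        fm, labels, folds, _ = separable_dataset
        result = mvpkit.run_cv(fm, labels, folds, svc_pipeline)
        tested = np.concatenate([f.test_indices for f in result.per_fold])
        np.testing.assert_array_equal(np.sort(tested), np.arange(fm.n_samples))

    def test_label_permutation_hits_chance_band(self, null_dataset,
                                                svc_pipeline):
        """Mean accuracy over 50 permuted-label runs in the 99% band of 0.5."""
        fm, labels, folds, _ = null_dataset
        accs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            perm = LabelVector("classification", rng.permutation(labels.values))
            accs.append(mvpkit.run_cv(fm, perm, folds, svc_pipeline).statistic)
        total = 50 * fm.n_samples
        band = 2.576 * np.sqrt(0.25 / total)
        assert abs(np.mean(accs) - 0.5) < band + 0.01

    def test_duplicated_halves_give_identical_folds(self, rng, svc_pipeline):
        X = rng.normal(size=(10, 6))
        y = np.r_[np.ones(5), -np.ones(5)]
        X2, y2 = np.vstack([X, X]), np.r_[y, y]
        folds = FoldAssignment(np.r_[np.ones(10), np.full(10, 2)], 2)
        result = mvpkit.run_cv(X2, LabelVector("classification", y2), folds,
                               svc_pipeline)
        f1, f2 = result.per_fold
        assert f1.metrics == f2.metrics

    def test_missing_class_in_training_split_names_fold(self, rng,
                                                        svc_pipeline):
        X = rng.normal(size=(6, 3))
        y = LabelVector("classification", [1, 1, 1, 1, -1, -1])
        folds = FoldAssignment([1, 1, 2, 2, 3, 3], 3)  # fold 3 holds all -1
        with pytest.raises(DataError, match="fold 3"):
            mvpkit.run_cv(X, y, folds, svc_pipeline)

    def test_pooled_accuracy_is_weighted_fold_mean(self, rng, svc_pipeline):
        X = rng.normal(size=(10, 4))
        X[:5] += 1.0
        y = LabelVector("classification", np.r_[np.ones(5), -np.ones(5)])
        folds = mvpkit.random_folds(10, 4, y, seed=0)  # uneven folds
        result = mvpkit.run_cv(X, y, folds, svc_pipeline)
        weighted = sum(f.metrics["accuracy"] * len(f.test_indices)
                       for f in result.per_fold) / 10
        assert result.aggregate["accuracy"] == pytest.approx(weighted)

    def test_mean_weights_is_elementwise_fold_mean(self, separable_dataset,
                                                   svc_pipeline):
        fm, labels, folds, _ = separable_dataset
        result = mvpkit.run_cv(fm, labels, folds, svc_pipeline)
        stack = np.vstack([f.weights[0] for f in result.per_fold])
        np.testing.assert_allclose(result.mean_weights, stack.mean(axis=0))

    def test_engine_level_leakage_guard(self, rng):
        """Perturbing a test-fold sample leaves that fold's fit unchanged."""
        X = rng.normal(size=(12, 5))
        y = LabelVector("classification", np.r_[np.ones(6), -np.ones(6)])
        folds = mvpkit.random_folds(12, 3, y, seed=0)
        pipe = mvpkit.Pipeline(
            model=mvpkit.make_model("svm"),
            steps=(mvpkit.ZScoreStep(), mvpkit.PCAStep(variance_threshold=1.0),
                   mvpkit.SelectStep(amount=3, method="fscore")))
        base = mvpkit.run_cv(X, y, folds, pipe, seed=0)
        te1 = folds.test_indices(1)
        X2 = X.copy()
        X2[te1] += rng.normal(scale=50.0, size=(len(te1), 5))
        alt = mvpkit.run_cv(X2, y, folds, pipe, seed=0)
        # fold 1's fitted weights depend only on its training split
        np.testing.assert_allclose(base.per_fold[0].weights[0],
                                   alt.per_fold[0].weights[0])

    def test_regression_pipeline_recovers_scores(self):
        spec = mvpkit.FixtureSpec(task="regress", seed=21, n_subjects=20,
                                  n_folds=20, regression_slope=0.02,
                                  noise_sd=0.5)
        vols, scores, folds, space = mvpkit.regression_dataset(spec)
        fm = synthetic.as_feature_matrix(vols, space)
        pipe = mvpkit.Pipeline(model=mvpkit.make_model("svm", "regress"))
        result = mvpkit.run_cv(fm, scores, folds, pipe)
        assert result.statistic >= 0.9


class TestRocAuc:
    def test_perfect_separation(self):
        y = LabelVector("classification", [1, 1, -1, -1])
        _, _, auc = mvpkit.roc_auc([2.0, 1.0, -1.0, -2.0], y)
        assert auc == 1.0

    def test_tie_matches_pairwise_concordance_oracle(self):
        scores = np.array([0.9, 0.5, 0.5, 0.3, 0.2, 0.1])
        y = np.array([1, 1, -1, 1, -1, -1], dtype=float)
        # brute force: P(s+ > s-) + 0.5 P(s+ = s-)
        pos, neg = scores[y == 1], scores[y == -1]
        pairs = [(a, b) for a in pos for b in neg]
        oracle = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                          for a, b in pairs])
        _, _, auc = mvpkit.roc_auc(scores, y)
        assert auc == pytest.approx(oracle)

    def test_null_auc_near_half(self, rng):
        aucs = []
        for _ in range(50):
            scores = rng.normal(size=40)
            y = rng.permutation(np.r_[np.ones(20), -np.ones(20)])
            aucs.append(mvpkit.roc_auc(scores, y)[2])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            mvpkit.roc_auc([1.0, 2.0], np.ones(2))


class TestPredictionPrecision:
    def test_identity_and_negation(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert mvpkit.prediction_precision(v, v) == pytest.approx(1.0)
        assert mvpkit.prediction_precision(-v, v) == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        assert mvpkit.prediction_precision(
            [1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            mvpkit.prediction_precision([1, 1, 1], [1, 2, 3])
        with pytest.raises(DataError):
            mvpkit.prediction_precision([1, 2], [1, 2])
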
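"""Transforms and selection: worked examples, oracles, leakage guards."""

import numpy as np
import pytest
from scipy import stats as sps

import mvpkit
from mvpkit import preprocess as pp
from mvpkit.data_io import DataError, LabelVector


class TestZScore:
    def test_column_direction_training_statistics(self):
        train = np.array([[1.0], [2.0], [3.0]])
        tr, te, params = pp.zscore_fit_apply(train, np.array([[4.0]]))
        assert params.m[0] == 2.0 and params.sigma[0] == pytest.approx(1.0)
        np.testing.assert_allclose(tr.ravel(), [-1, 0, 1])
        assert te[0, 0] == pytest.approx(2.0)

    def test_constant_column_maps_to_zero(self):
        train = np.full((4, 2), 7.0)
        train[:, 1] = [0, 1, 2, 3]
        tr, te, _ = pp.zscore_fit_apply(train, np.array([[9.0, 1.0]]))
        assert np.all(tr[:, 0] == 0) and te[0, 0] == 0
        assert np.isfinite(te).all()

    def test_row_direction_population_sigma(self):
        """Hand evaluation of Z=(x-m)/sigma with population SD per row."""
        row = np.array([[2.0, 4.0, 6.0]])
        tr, _, params = pp.zscore_fit_apply(row, direction="rows")
        sigma = np.std([2, 4, 6])  # ddof=0
        np.testing.assert_allclose(tr.ravel(), (row.ravel() - 4.0) / sigma)
        np.testing.assert_allclose(tr.ravel(), [-1.2247, 0, 1.2247], atol=1e-4)
        assert params.direction == "rows"

    def test_column_train_statistics_have_unit_variance(self, rng):
        X = rng.normal(2.0, 3.0, size=(10, 6))
        tr, _, _ = pp.zscore_fit_apply(X)
        np.testing.assert_allclose(tr.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(tr.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_leakage_guard_test_values_never_enter_fit(self, rng):
        train = rng.normal(size=(8, 5))
        t1 = rng.normal(size=(3, 5))
        t2 = t1 + 100.0
        _, _, p1 = pp.zscore_fit_apply(train, t1)
        _, _, p2 = pp.zscore_fit_apply(train, t2)
        np.testing.assert_array_equal(p1.m, p2.m)
        np.testing.assert_array_equal(p1.sigma, p2.sigma)


class TestPCA:
    def test_degenerate_variance_keeps_one_component(self, rng):
        X = np.zeros((6, 2))
        X[:, 0] = rng.normal(size=6)
        params = pp.pca_fit(X, variance_threshold=0.95)
        assert params.n_kept == 1

    def test_threshold_one_keeps_rank_cap(self, rng):
        X = rng.normal(size=(6, 10))
        params = pp.pca_fit(X, variance_threshold=1.0)
        assert params.n_kept == min(6 - 1, 10)

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(6, 10))
        params = pp.pca_fit(X, variance_threshold=1.0)
        # brute-force oracle: eigenvectors of the centered covariance
        C = np.cov(X - X.mean(axis=0), rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        for j in range(params.n_kept):
            dot = abs(evecs[:, order[j]] @ params.component_loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_kept_variance_rule_boundary(self, rng):
        X = rng.normal(size=(12, 8))
        params = pp.pca_fit(X, variance_threshold=0.8)
        cum = np.cumsum(params.explained_variance_fraction)
        assert cum[-1] >= 0.8
        if params.n_kept > 1:
            assert cum[-2] < 0.8

    def test_apply_matches_direct_projection(self, rng):
        X = rng.normal(size=(6, 4))
        params = pp.pca_fit(X, variance_threshold=1.0)
        held_out = rng.normal(size=(1, 4))
        expected = (held_out - X.mean(axis=0)) @ params.component_loadings
        np.testing.assert_allclose(pp.pca_apply(params, held_out), expected)

    def test_full_rank_reconstruction_and_mean_sample(self, rng):
        X = rng.normal(size=(5, 3))
        params = pp.pca_fit(X, variance_threshold=1.0)
        scores = pp.pca_apply(params, X)
        recon = scores @ params.component_loadings.T + params.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)
        mean_scores = pp.pca_apply(params, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(mean_scores, 0, atol=1e-10)

    def test_explicit_n_beyond_cap_rejected(self, rng):
        X = rng.normal(size=(4, 10))
        with pytest.raises(DataError, match="cap"):
            pp.pca_fit(X, n_components=5)

    def test_leakage_guard(self, rng):
        train = rng.normal(size=(8, 5))
        p1 = pp.pca_fit(train)
        p2 = pp.pca_fit(train)  # refitting is a pure function of train
        np.testing.assert_array_equal(p1.component_loadings,
                                      p2.component_loadings)


class TestFScore:
    def test_hand_computed_anova(self):
        """A=(0,1), B=(2,3): MSb=4, MSw=0.5 -> F=8."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = LabelVector("classification", [1, 1, -1, -1])
        assert pp.fscore_rank(X, y)[0] == pytest.approx(8.0)

    def test_identical_feature_scores_zero(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        y = LabelVector("classification", [1, 1, -1, -1])
        assert pp.fscore_rank(X, y)[0] == 0.0

    def test_zero_within_class_variance_is_infinite(self):
        X = np.array([[0.0, 5.0], [0.0, 6.0], [1.0, 7.0], [1.0, 8.0]])
        y = LabelVector("classification", [1, 1, -1, -1])
        F = pp.fscore_rank(X, y)
        assert np.isinf(F[0]) and np.isfinite(F[1])
        assert pp.select_features(F, 1).selected[0] == 0

    def test_matches_scipy_f_oneway(self, rng):
        X = rng.normal(size=(12, 6))
        y = LabelVector("classification", np.r_[np.ones(6), -np.ones(6)])
        F = pp.fscore_rank(X, y)
        for j in range(6):
            ref = sps.f_oneway(X[:6, j], X[6:, j]).statistic
            assert F[j] == pytest.approx(ref)

    def test_shift_invariance(self, rng):
        X = rng.normal(size=(10, 4))
        y = LabelVector("classification", np.r_[np.ones(5), -np.ones(5)])
        np.testing.assert_allclose(pp.fscore_rank(X, y),
                                   pp.fscore_rank(X + 17.0, y))

    def test_regression_branch_matches_correlation_f(self, rng):
        X = rng.normal(size=(15, 3))
        y = LabelVector("regression", rng.normal(size=15))
        F = pp.fscore_rank(X, y)
        for j in range(3):
            r = sps.pearsonr(X[:, j], y.values)[0]
            assert F[j] == pytest.approx(13 * r**2 / (1 - r**2))

    def test_tiny_class_rejected(self):
        X = np.zeros((3, 2))
        y = LabelVector("classification", [1, -1, -1])
        with pytest.raises(DataError):
            pp.fscore_rank(X, y)


class TestWeightRank:
    def test_separating_feature_gets_largest_weight(self, rng):
        n = 20
        X = rng.normal(size=(n, 5)) * 0.1
        y = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        X[:, 0] += 3.0 * y  # only feature 0 separates
        spec = mvpkit.make_model("svm", "classify")
        scores = pp.weight_rank(X, LabelVector("classification", y), spec)
        assert np.argmax(scores) == 0

    def test_duplicated_features_score_equally(self, rng):
        X = rng.normal(size=(12, 3))
        X = np.hstack([X, X[:, :1]])  # column 3 duplicates column 0
        y = LabelVector("classification", np.r_[np.ones(6), -np.ones(6)])
        scores = pp.weight_rank(X, y, mvpkit.make_model("svm", "classify"))
        assert scores[0] == pytest.approx(scores[3], rel=1e-6)

    def test_nonlinear_model_refused(self, rng):
        X = rng.normal(size=(8, 2))
        y = LabelVector("classification", np.r_[np.ones(4), -np.ones(4)])
        spec = mvpkit.make_model("svm", "classify", {"kernel": "rbf"})
        with pytest.raises(DataError, match="weights undefined"):
            pp.weight_rank(X, y, spec)


class TestSelectFeatures:
    def test_fraction_of_hundred(self, rng):
        scores = rng.permutation(100).astype(float)
        sel = pp.select_features(scores, 0.10)
        assert len(sel.selected) == 10
        assert set(sel.selected) == set(np.argsort(scores)[-10:])

    def test_fraction_one_keeps_everything(self):
        scores = np.array([3.0, 1.0, 2.0])
        sel = pp.select_features(scores, 1.0)
        assert sorted(sel.selected) == [0, 1, 2]

    def test_ties_break_to_lower_index(self):
        sel = pp.select_features(np.zeros(10), 3)
        np.testing.assert_array_equal(sel.selected, [0, 1, 2])

    def test_prefix_property(self, rng):
        scores = rng.integers(0, 5, size=20).astype(float)  # many ties
        for n in range(1, 20):
            a = pp.select_features(scores, n).selected
            b = pp.select_features(scores, n + 1).selected
            np.testing.assert_array_equal(a, b[:n])

    def test_over_selection_rejected(self):
        with pytest.raises(DataError):
            pp.select_features(np.ones(5), 6)


class TestLasso:
    def test_unpenalized_limit_selects_everything(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5)
        sel = pp.lasso_select(X, y, pp.LassoConfig(lam=0.0))
        assert len(sel.selected) == 5

    def test_full_shrinkage_is_an_error(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        with pytest.raises(DataError, match="empty selection"):
            pp.lasso_select(X, y, pp.LassoConfig(lam=1e6))

    def test_recovers_true_support(self):
        """y = 2 x1 - 3 x2 + noise: features 0, 1 recovered in >=95% of runs."""
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(100, 20))
            y = 2 * X[:, 0] - 3 * X[:, 1] + rng.normal(0, 0.1, size=100)
            sel = pp.lasso_select(X, y, pp.LassoConfig(seed=rep))
            if {0, 1} <= set(sel.selected.tolist()):
                hits += 1
        assert hits >= 48  # 95% of 50, with a little slack above it

    def test_inner_cv_is_deterministic(self, rng):
        X = rng.normal(size=(30, 8))
        y = X[:, 0] + rng.normal(0, 0.5, size=30)
        s1 = pp.lasso_select(X, y, pp.LassoConfig(seed=5))
        s2 = pp.lasso_select(X, y, pp.LassoConfig(seed=5))
        np.testing.assert_array_equal(s1.selected, s2.selected)
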
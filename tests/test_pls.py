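"""PLS1 core, cross-validation, rank selection, PCA, validation metrics."""

import numpy as np
import pytest
from scipy import stats

from nirspeclib import (
    PLS1Model,
    fit_pls1,
    loocv,
    pca_scores,
    select_rank_ftest,
    validation_metrics,
)
from nirspeclib.errors import (
    DataError,
    DegenerateInputError,
    RankError,
    ValidationError,
)


def random_system(seed, n=20, p=8, noise=0.0):
    gen = np.random.default_rng(seed)
    X = gen.normal(size=(n, p))
    b = gen.normal(size=p)
    y = X @ b + noise * gen.normal(size=n)
    return X, y


class TestFitPLS1:
    def test_exact_fit_on_noiseless_linear_data(self):
        X, y = random_system(0)
        res = fit_pls1(X, y, rank=8)
        np.testing.assert_allclose(res.predict_features(X), y, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_equals_least_squares(self, seed):
        # oracle: explicit normal-equations solve
        X, y = random_system(seed, noise=0.3)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        res = fit_pls1(X, y, rank=8)
        np.testing.assert_allclose(res.regression_vector, b_ols, atol=1e-8)
        np.testing.assert_allclose(
            res.predict_features(X), y.mean() + Xc @ b_ols, atol=1e-8
        )

    def test_matches_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_system(3, n=30, p=12, noise=0.2)
        for rank in (1, 3, 5):
            res = fit_pls1(X, y, rank)
            ref = sklearn.PLSRegression(n_components=rank, scale=False).fit(
                X, y[:, None]
            )
            np.testing.assert_allclose(
                res.predict_features(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_rank_too_large_rejected(self):
        X, y = random_system(0, n=5, p=8)
        with pytest.raises(RankError):
            fit_pls1(X, y, rank=5)  # limit is n-1 = 4

    def test_zero_variance_y_rejected(self):
        X, _ = random_system(0)
        with pytest.raises(DegenerateInputError):
            PLS1Model(X, np.full(20, 3.0))

    def test_invariant_to_sample_reordering(self):
        X, y = random_system(4, noise=0.2)
        perm = np.random.default_rng(0).permutation(len(y))
        res1 = fit_pls1(X, y, 4)
        res2 = fit_pls1(X[perm], y[perm], 4)
        probe = np.random.default_rng(1).normal(size=(5, X.shape[1]))
        np.testing.assert_allclose(
            res1.predict_features(probe), res2.predict_features(probe), atol=1e-8
        )

    def test_training_residuals_non_increasing_in_rank(self):
        X, y = random_system(5, noise=0.5)
        rss = []
        for rank in range(1, 9):
            res = fit_pls1(X, y, rank)
            rss.append(np.sum((y - res.predict_features(X)) ** 2))
        assert all(a >= b - 1e-10 for a, b in zip(rss, rss[1:]))

    def test_summary_is_text(self):
        X, y = random_system(0)
        text = fit_pls1(X, y, 3).summary()
        assert "Rank" in text and "PLS1" in text


class TestLOOCV:
    def test_matches_literal_holdout_loop(self):
        # oracle: independent re-implementation by literal looping
        X, y = random_system(7, n=12, p=6, noise=0.4)
        rmsecv, press = loocv(X, y, max_rank=5)
        for rank in range(1, 6):
            preds = np.empty(12)
            for i in range(12):
                keep = np.arange(12) != i
                res = fit_pls1(X[keep], y[keep], rank)
                preds[i] = res.predict_features(X[i][None, :])[0]
            press_naive = np.sum((y - preds) ** 2)
            assert press[rank - 1] == pytest.approx(press_naive, abs=1e-10)
            assert rmsecv[rank - 1] == pytest.approx(
                np.sqrt(press_naive / 12), abs=1e-10
            )

    def test_noiseless_linear_data_generalizes_exactly(self):
        X, y = random_system(8, n=12, p=6, noise=0.0)
        rmsecv, _ = loocv(X, y, max_rank=6)
        assert rmsecv[-1] <= 1e-6

    def test_infeasible_rank_rejected(self):
        X, y = random_system(0, n=6, p=8)
        with pytest.raises(RankError):
            loocv(X, y, max_rank=5)  # limit is n-2 = 4


class TestSelectRankFtest:
    def test_single_entry(self):
        assert select_rank_ftest([4.2], n=10) == 1

    def test_parsimony_example(self):
        # ranks 2..4 all within F-threshold of the minimum; smallest wins
        press = [100.0, 10.0, 9.99, 9.98]
        assert select_rank_ftest(press, n=1000, alpha=0.25) == 2
        # cross-check the threshold arithmetic explicitly
        thr = stats.f.ppf(0.75, 1000, 1000)
        assert 100.0 / 9.98 > thr and 10.0 / 9.98 < thr

    def test_isolated_minimum_takes_last_rank(self):
        press = [100.0, 50.0, 25.0, 2.0]
        assert select_rank_ftest(press, n=20, alpha=0.25) == 4

    def test_invalid_press_rejected(self):
        with pytest.raises(ValidationError):
            select_rank_ftest([1.0, -2.0], n=10)


class TestValidationMetrics:
    def test_press_and_rmsep_arithmetic(self):
        rep = validation_metrics([1.0, 2.0], [0.0, 0.0], mode="tsv")
        assert rep.press == pytest.approx(5.0)
        assert rep.rmsep == pytest.approx(np.sqrt(2.5))
        assert rep.rmsecv is None

    def test_perfect_predictions(self):
        rep = validation_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.r_squared == pytest.approx(100.0)
        assert rep.frac_lt_1pct == 1.0
        assert rep.frac_gt_5pct == 0.0
        assert rep.mean_abs_differ == 0.0

    def test_threshold_fractions(self):
        rep = validation_metrics([10.0, 10.0], [9.5, 16.0])
        assert rep.frac_gt_5pct == pytest.approx(0.5)
        assert rep.frac_lt_1pct == pytest.approx(0.5)

    def test_rmsep_squared_times_n_is_press(self, rng):
        y = rng.normal(size=17)
        yp = y + rng.normal(size=17)
        rep = validation_metrics(y, yp)
        assert rep.rmsep**2 * rep.n == pytest.approx(rep.press, abs=1e-10)

    def test_r_squared_identity(self, rng):
        y = rng.normal(loc=50, scale=5, size=25)
        yp = y + rng.normal(size=25)
        rep = validation_metrics(y, yp)
        tss = np.sum((y - y.mean()) ** 2)
        assert rep.r_squared == pytest.approx(
            100.0 * (1 - rep.press / tss), abs=1e-10
        )

    def test_loocv_mode_reports_rmsecv(self):
        rep = validation_metrics([1.0, 2.0], [1.1, 2.1], mode="loocv")
        assert rep.rmsecv is not None and rep.rmsep is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            validation_metrics([1.0], [1.0, 2.0])


class TestPCAScores:
    def test_collinear_points_have_null_second_component(self):
        t = np.linspace(0, 1, 12)
        X = np.outer(t, [1.0, 2.0])
        scores = pca_scores(X, 2)
        assert np.max(np.abs(scores[:, 1])) <= 1e-10

    def test_scores_covariance_diagonal(self, rng):
        X = rng.normal(size=(30, 6))
        scores = pca_scores(X, 4)
        cov = scores.T @ scores
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) <= 1e-8
        assert all(np.diff(np.diag(cov)) <= 1e-8)  # non-increasing variance

    def test_matches_eigendecomposition(self, rng):
        # oracle: direct eigensolver on the small covariance matrix
        X = rng.normal(size=(15, 5))
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        scores = pca_scores(X, 3)
        for j in range(3):
            v = evecs[:, j]
            k = np.argmax(np.abs(v))
            if v[k] < 0:
                v = -v
            np.testing.assert_allclose(scores[:, j], Xc @ v, atol=1e-8)

    def test_infeasible_components_rejected(self, rng):
        with pytest.raises(RankError):
            pca_scores(rng.normal(size=(4, 10)), 4)
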
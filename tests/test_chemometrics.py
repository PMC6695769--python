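"""Tests of splitting, PCA screening, PLS and cross-validation."""

import numpy as np
import pytest
from scipy import stats as sps

from vinespec.chemometrics import (
    CalibrationDataset,
    control_limits,
    cross_validate,
    detect_outliers,
    model_statistics,
    pca_fit,
    pls_fit,
    q_statistic,
    r_squared,
    rmse,
    split_dataset,
    t2_statistic,
    venetian_blinds_folds,
)


class TestSplit:
    def test_80_20_split_of_144_gives_116_28(self):
        y = np.linspace(0, 1, 144)
        labels = split_dataset(y, 0.8, seed=0)
        assert int(np.sum(labels == "calibration")) == 116
        assert int(np.sum(labels == "validation")) == 28

    def test_two_samples_split_one_one(self):
        labels = split_dataset(np.array([1.0, 2.0]), 0.5, seed=1)
        assert sorted(labels) == ["calibration", "validation"]

    def test_validation_range_is_inside_full_range(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=100)
        for seed in range(5):
            labels = split_dataset(y, 0.8, seed=seed)
            val = y[labels == "validation"]
            assert val.min() >= y.min() and val.max() <= y.max()

    def test_calibration_covers_the_response_range_across_seeds(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=144)
        full = np.ptp(y)
        for seed in range(20):
            labels = split_dataset(y, 0.8, seed=seed)
            cal = y[labels == "calibration"]
            assert np.ptp(cal) >= 0.9 * full

    def test_stratification_spreads_validation_over_rank_bins(self):
        y = np.arange(144, dtype=float)
        labels = split_dataset(y, 0.8, seed=4)
        val_ranks = np.sort(np.flatnonzero(labels == "validation"))
        # consecutive validation picks come from consecutive rank bins of
        # width ~5.14, so gaps can never exceed two bin widths
        assert np.all(np.diff(val_ranks) <= 11)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.arange(10.0), 1.0, seed=0)
        with pytest.raises(ValueError):
            split_dataset(np.arange(10.0), 0.0, seed=0)


class TestPCA:
    def test_identical_rows_have_zero_variance(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (6, 1))
        model = pca_fit(X, k=2)
        assert model.eigenvalues == pytest.approx(np.zeros(2), abs=1e-24)
        assert model.scores(X) == pytest.approx(np.zeros((6, 2)), abs=1e-12)

    def test_rank_one_matrix_reconstructs_exactly(self):
        t = np.arange(1.0, 9.0)
        v = np.array([0.5, -1.0, 2.0])
        X = np.outer(t, v)
        model = pca_fit(X, k=1)
        assert q_statistic(X, model) == pytest.approx(np.zeros(8), abs=1e-18)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 8))
        model = pca_fit(X, k=8)
        evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
        evals, evecs = evals[::-1], evecs[:, ::-1]
        assert model.all_eigenvalues == pytest.approx(evals, abs=1e-8)
        for j in range(8):
            dot = abs(model.loadings[:, j] @ evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_k_out_of_range_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            pca_fit(X, k=5)


class TestQT2:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 6))
        return X, pca_fit(X, k=3)

    def test_mean_sample_has_zero_statistics(self, model):
        X, pca = model
        assert q_statistic(pca.mean, pca) == pytest.approx(0.0, abs=1e-20)
        assert t2_statistic(pca.mean, pca) == pytest.approx(0.0, abs=1e-20)

    def test_sample_along_first_loading_has_closed_form_t2(self, model):
        X, pca = model
        c = 1.7
        x = pca.mean + c * pca.loadings[:, 0]
        assert q_statistic(x, pca) == pytest.approx(0.0, abs=1e-15)
        assert t2_statistic(x, pca) == pytest.approx(
            c**2 / pca.eigenvalues[0], rel=1e-10)

    def test_statistics_match_brute_force_projection(self, model):
        X, pca = model
        P = pca.loadings
        for x in X[:10]:
            xc = x - pca.mean
            proj = P @ (P.T @ xc)
            q_oracle = float((xc - proj) @ (xc - proj))
            t = P.T @ xc
            t2_oracle = float(np.sum(t**2 / pca.eigenvalues))
            assert abs(q_statistic(x, pca) - q_oracle) < 1e-10
            assert abs(t2_statistic(x, pca) - t2_oracle) < 1e-10


class TestControlLimits:
    def test_t2_limit_approaches_chi_squared_for_large_n(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(100_000, 4))
        pca = pca_fit(X, k=1)
        _, t2_limit = control_limits(pca, alpha=0.95)
        assert t2_limit == pytest.approx(sps.chi2.ppf(0.95, 1), rel=5e-4)

    def test_limits_increase_with_confidence(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 10))
        pca = pca_fit(X, k=3)
        q50, t50 = control_limits(pca, alpha=0.5)
        q99, t99 = control_limits(pca, alpha=0.99)
        assert q99 > q50 and t99 > t50

    def test_degenerate_requests_rejected(self):
        from vinespec.chemometrics import PCAModel

        rng = np.random.default_rng(14)
        pca = pca_fit(rng.normal(size=(20, 10)), k=3)
        with pytest.raises(ValueError):
            control_limits(pca, alpha=1.5)
        tiny = PCAModel(
            mean=pca.mean, loadings=pca.loadings,
            eigenvalues=pca.eigenvalues,
            all_eigenvalues=pca.all_eigenvalues, n_samples=3)
        with pytest.raises(ValueError):
            control_limits(tiny, alpha=0.99)


class TestOutliers:
    def test_clean_synthetic_dataset_has_no_flags(self, treated_d1w15):
        flags, _ = detect_outliers(treated_d1w15)
        assert int(flags.sum()) == 0

    def test_amplitude_spike_is_flagged(self, treated_d1w15):
        X = treated_d1w15.copy()
        X[7] = 10.0 * X[7]
        flags, _ = detect_outliers(X)
        assert flags[7]
        assert int(flags.sum()) <= 2

    def test_single_sample_warns_and_passes(self):
        with pytest.warns(UserWarning):
            flags, model = detect_outliers(np.ones((1, 5)))
        assert flags.tolist() == [False] and model is None


class TestPLS:
    def test_univariate_collapses_to_least_squares_line(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=(30, 1))
        y = 2.0 + 3.0 * x[:, 0] + rng.normal(0, 0.1, 30)
        model = pls_fit(x, y, n_lv=1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        assert model.coef[0] == pytest.approx(slope, rel=1e-10)
        assert model.predict(np.zeros((1, 1)))[0] == pytest.approx(
            intercept, rel=1e-8)

    def test_full_rank_equals_least_squares_predictions(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        model = pls_fit(X, y, n_lv=8)
        xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(xc, y - y.mean(), rcond=None)
        oracle = y.mean() + xc @ beta
        assert model.predict(X) == pytest.approx(oracle, abs=1e-8)

    def test_exact_recovery_of_three_factor_response(self):
        rng = np.random.default_rng(22)
        T = rng.normal(size=(40, 3))
        P = rng.normal(size=(3, 12))
        X = T @ P
        y = T @ np.array([1.0, -2.0, 0.5])
        model = pls_fit(X, y, n_lv=3)
        assert np.max(np.abs(model.predict(X) - y)) < 1e-8

    def test_deterministic(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        a = pls_fit(X, y, n_lv=5)
        b = pls_fit(X, y, n_lv=5)
        assert np.array_equal(a.coef, b.coef)

    def test_agrees_with_reference_implementation(self):
        """Independent cross-check against scikit-learn's NIPALS PLS."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(24)
        X = rng.normal(size=(30, 20))
        y = X[:, :4] @ np.array([1.0, 0.5, -1.0, 2.0]) + rng.normal(0, 0.2, 30)
        ours = pls_fit(X, y, n_lv=4)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        assert ours.predict(X) == pytest.approx(
            ref.predict(X).ravel(), abs=1e-8)

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            pls_fit(X, np.ones(10), n_lv=2)  # zero-variance y
        with pytest.raises(ValueError):
            pls_fit(X, rng.normal(size=10), n_lv=11)


class TestVenetianBlinds:
    def test_each_fold_gets_one_of_ten(self):
        folds = venetian_blinds_folds(10, 10)
        assert sorted(folds) == list(range(10))

    def test_116_samples_in_10_folds(self):
        folds = venetian_blinds_folds(116, 10)
        sizes = np.bincount(folds)
        assert sorted(sizes.tolist()) == [11] * 4 + [12] * 6
        assert folds[:12].tolist() == [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 0, 1]

    def test_labels_follow_dataset_order(self):
        folds = venetian_blinds_folds(7, 3)
        assert folds.tolist() == [0, 1, 2, 0, 1, 2, 0]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            venetian_blinds_folds(5, 10)


class TestCrossValidate:
    def test_noiseless_factor_model_selects_few_lvs(self):
        rng = np.random.default_rng(30)
        T = rng.normal(size=(60, 3))
        P = rng.normal(size=(3, 30))
        X = T @ P
        y = T @ np.array([2.0, -1.0, 0.7])
        cv = cross_validate(X, y, max_lv=10, n_folds=10)
        assert cv.rmsecv[2] < 1e-6 * np.std(y)
        assert cv.n_lv <= 4

    def test_every_sample_held_out_once(self):
        n = 53
        folds = venetian_blinds_folds(n, 10)
        held = np.zeros(n, dtype=int)
        for f in range(10):
            held[folds == f] += 1
        assert np.all(held == 1)

    def test_pure_noise_response_selects_small_model(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(60, 30))
        y = rng.normal(size=60)
        cv = cross_validate(X, y, max_lv=10, n_folds=10)
        assert cv.n_lv <= 3

    def test_max_lv_one_selects_one(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(30, 10))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        assert cross_validate(X, y, max_lv=1, n_folds=10).n_lv == 1


class TestStatistics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert rmse(y, y) == 0.0
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.full(4, y.mean())
        assert r_squared(y, yhat) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_four_sample_fixture(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.5, 1.5, 3.5, 3.5])
        # residuals 0.5 each -> RMSE 0.5; SSE = 1.0, SST = 5.0
        assert rmse(y, yhat) == pytest.approx(0.5)
        assert r_squared(y, yhat) == pytest.approx(1.0 - 1.0 / 5.0)

    def test_corr_mode_is_squared_pearson(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = 2.0 * y + 1.0  # biased but perfectly correlated
        assert r_squared(y, yhat, mode="corr") == pytest.approx(1.0)
        assert r_squared(y, yhat) < 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.empty(0), np.empty(0))

    def test_rmsec_typically_below_rmsecv(self):
        """Training error should not exceed cross-validation error, as a
        median over 20 simulated calibrations."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            T = rng.normal(size=(50, 3))
            X = T @ rng.normal(size=(3, 25)) + rng.normal(0, 0.1, (50, 25))
            y = T @ np.array([1.0, -0.5, 0.3]) + rng.normal(0, 0.3, 50)
            cv = cross_validate(X, y, max_lv=8, n_folds=10)
            model = pls_fit(X, y, cv.n_lv)
            diffs.append(rmse(y, cv.cv_predictions) - rmse(y, model.predict(X)))
        assert np.median(diffs) > 0

    def test_model_statistics_assembles_all_fields(self, treated_d1w15,
                                                   dataset):
        from vinespec.chemometrics import train_analyte

        sub = CalibrationDataset(
            X=treated_d1w15, y=dict(dataset.y),
            block_ids=list(dataset.block_ids),
            date_indices=dataset.date_indices)
        model, stats, cv = train_analyte(sub, "tss", treatment="D1W15",
                                         seed=0)
        assert stats.n_calibration == 116 and stats.n_validation == 28
        assert stats.rmsec >= 0 and stats.r2_c <= 1
        assert stats.n_lv == cv.n_lv == model.n_lv
        lo, hi = stats.range_reference
        assert 10.7 <= lo < hi <= 25.2
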
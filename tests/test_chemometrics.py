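"""PLS engine: fitting, cross-validation, filtering, bias, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stalkscreen import chemometrics as cm
from stalkscreen.preprocess import PreprocessRecipe
from stalkscreen.spectra import SpectraSet


def random_instance(seed, n=20, p=10, m=1, noise=0.1, rank=None):
    rng = np.random.default_rng(seed)
    if rank is not None and rank < p:
        basis = rng.normal(size=(rank, p))
        X = rng.normal(size=(n, rank)) @ basis
    else:
        X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + noise * rng.normal(size=(n, m))
    return X, Y


class TestFit:
    def test_exact_univariate_linear_system(self):
        # y proportional to one predictor column, zero noise, mutually
        # orthogonal centred predictors: one LV gives an exact fit
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(15, 6))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = 2.5 * X[:, 2]
        model = cm.fit_pls(X, y, n_lv=1)
        pred = model.predict_matrix(X)[:, 0]
        assert model.training_metrics["y0"].r2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(pred, y, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_least_squares(self, seed):
        X, Y = random_instance(seed, n=25, p=8, m=2)
        Xc = X - X.mean(axis=0)
        model = cm.fit_pls(X, Y, n_lv=8)
        ls = Xc @ np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)[0] \
            + Y.mean(axis=0)
        np.testing.assert_allclose(model.predict_matrix(X), ls, rtol=1e-8,
                                   atol=1e-8)

    def test_rank_deficient_equals_least_squares(self):
        X, Y = random_instance(11, n=30, p=50, m=1, rank=6)
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        model = cm.fit_pls(X, Y, n_lv=rank)
        Xc = X - X.mean(axis=0)
        ls = Xc @ np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)[0] \
            + Y.mean(axis=0)
        np.testing.assert_allclose(model.predict_matrix(X), ls, rtol=1e-8,
                                   atol=1e-8)

    def test_scores_orthogonal(self):
        X, Y = random_instance(3, n=25, p=12, m=2)
        model = cm.fit_pls(X, Y, n_lv=6)
        T = model.scores(X)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_rmsec_non_increasing_in_n_lv(self):
        X, Y = random_instance(4, n=25, p=10, m=1)
        rmsec = [cm.fit_pls(X, Y, k).training_metrics["y0"].rmsec
                 for k in range(1, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(rmsec, rmsec[1:]))

    @pytest.mark.parametrize("n_lv", [0, 12, 20])
    def test_n_lv_bounds(self, n_lv):
        # n_lv must satisfy 1 <= n_lv <= min(n_samples - 1, n_variables)
        X, Y = random_instance(5, n=12, p=30)
        with pytest.raises(ValueError, match="n_lv out of bounds"):
            cm.fit_pls(X, Y, n_lv)

    def test_nan_rejected(self):
        X, Y = random_instance(6)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cm.fit_pls(X, Y, 2)

    def test_against_sklearn_oracle(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, Y = random_instance(7, n=30, p=15, m=1)
        ours = cm.fit_pls(X, Y, 4).predict_matrix(X)
        ref = sklearn.PLSRegression(n_components=4, scale=False)
        ref.fit(X, Y)
        np.testing.assert_allclose(ours, ref.predict(X), rtol=1e-6, atol=1e-8)


class TestAlgorithmAgreement:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 3),
           n_lv=st.integers(1, 6))
    def test_nipals_vs_wide_kernel(self, seed, m, n_lv):
        X, Y = random_instance(seed, n=18, p=40, m=m)
        p1 = cm.fit_pls(X, Y, n_lv, "nipals").predict_matrix(X)
        p2 = cm.fit_pls(X, Y, n_lv, "wide_kernel").predict_matrix(X)
        scale = np.abs(p1).max()
        np.testing.assert_allclose(p1, p2, atol=1e-8 * max(scale, 1.0))


class TestCrossValidation:
    def test_noiseless_one_lv_system(self):
        X, Y = random_instance(8, n=15, p=6, noise=0.0, rank=1)
        cv = cm.cross_validate(X, Y, max_lv=3)
        assert cv.rmsecv[0, 0] <= 1e-8

    def test_loo_prediction_counts(self):
        X, Y = random_instance(9, n=10, p=5)
        cv = cm.cross_validate(X, Y, max_lv=3)
        assert cv.oof_predictions.shape == (3, 10, 1)
        assert np.isfinite(cv.oof_predictions).all()

    def test_loo_fold_equivalence(self):
        # the pooled out-of-fold prediction for sample i must equal a
        # manual fit on the other n-1 samples
        X, Y = random_instance(10, n=12, p=6)
        cv = cm.cross_validate(X, Y, max_lv=2)
        keep = np.ones(12, dtype=bool)
        keep[4] = False
        manual = cm.fit_pls(X[keep], Y[keep], 2).predict_matrix(X[4:5])
        np.testing.assert_allclose(cv.oof_predictions[1, 4], manual[0],
                                   atol=1e-10)

    def test_too_few_samples(self):
        X, Y = random_instance(0, n=2, p=4)
        with pytest.raises(ValueError, match="too few"):
            cm.cross_validate(X, Y, max_lv=1)


class TestSelectNLv:
    @pytest.mark.parametrize("table,expected", [
        ([5.0, 3.0, 3.5], 2),
        ([4.0, 4.0, 4.0], 1),          # tie -> fewest LVs
        ([3.02, 3.00, 2.999], 1),      # parsimony: within 1% of the minimum
        ([10.0, 5.0, 1.0, 0.999], 3),
    ])
    def test_selection_rule(self, table, expected):
        assert cm.select_n_lv(np.array(table)) == expected

    def test_empty_table(self):
        with pytest.raises(ValueError):
            cm.select_n_lv(np.array([]))


class TestJackknifeFilter:
    def test_informative_variables_kept_noise_removed(self):
        rng = np.random.default_rng(12)
        n, p_sig, p_noise = 40, 3, 12
        Xs = rng.normal(size=(n, p_sig))
        Xn = rng.normal(size=(n, p_noise)) * 0.01
        y = Xs @ np.array([3.0, -2.0, 1.5]) + 0.05 * rng.normal(size=n)
        X = np.hstack([Xs, Xn])
        mask = cm.jackknife_ci_filter(X, y, n_lv=3, alpha=0.10)
        assert mask[:p_sig].all()
        assert mask[p_sig:].sum() < p_noise

    def test_pure_noise_removes_most_variables(self):
        # on pure noise, roughly (1 - alpha) of coefficients should have
        # CIs spanning zero; simulation over repeated draws
        removed_fracs = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(12, 8))
            y = rng.normal(size=12)
            try:
                mask = cm.jackknife_ci_filter(X, y, n_lv=2, alpha=0.10)
                removed_fracs.append(1.0 - mask.mean())
            except ValueError:
                removed_fracs.append(1.0)  # everything removed
        assert np.mean(removed_fracs) >= 0.10

    def test_all_removed_raises(self):
        # pure-noise response with an essentially zero alpha makes every
        # confidence interval span zero
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        with pytest.raises(ValueError, match="empty model"):
            cm.jackknife_ci_filter(X, y, n_lv=2, alpha=1e-9)


class TestBiasCalibration:
    def test_perfect_predictions(self):
        ref = np.linspace(0, 10, 20)
        b = cm.calibrate_bias(ref, ref)
        assert b.offset == pytest.approx(0.0, abs=1e-10)
        assert b.slope_factor == 1.0

    def test_constant_offset(self):
        ref = np.linspace(0, 10, 20)
        b = cm.calibrate_bias(ref + 5.0, ref)
        assert b.offset == pytest.approx(5.0, abs=1e-10)
        assert b.slope_factor == 1.0
        np.testing.assert_allclose(b.apply(ref + 5.0), ref, atol=1e-10)

    def test_slope_adjustment(self):
        ref = np.linspace(0, 10, 20)
        b = cm.calibrate_bias(1.1 * ref, ref)
        assert b.slope_factor == pytest.approx(1 / 1.1, rel=1e-10)
        np.testing.assert_allclose(b.apply(1.1 * ref), ref, atol=1e-9)

    def test_dead_band_skips_small_slope_deviation(self):
        ref = np.linspace(0, 10, 20)
        b = cm.calibrate_bias(1.005 * ref, ref)
        assert b.slope_factor == 1.0

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cm.calibrate_bias(np.ones(5), np.ones(5))


class TestMetrics:
    def test_perfect(self):
        m = cm.regression_metrics([1, 2, 3], [1, 2, 3], "calibration")
        assert m.rmsec == 0.0 and m.r2 == pytest.approx(1.0)

    def test_unit_shift(self):
        m = cm.regression_metrics([2, 3, 4, 5], [1, 2, 3, 4], "validation")
        assert m.rmsep == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # pairs (pred, ref) = (1,2),(2,2),(3,5): SSE = 1+0+4 = 5,
        # SStot about ref mean 3 = 1+1+4 = 6
        m = cm.regression_metrics([1, 2, 3], [2, 2, 5], "validation")
        assert m.rmsep == pytest.approx(np.sqrt(5 / 3))
        assert m.q2 == pytest.approx(1 - 5 / 6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cm.regression_metrics([1, 2], [1, 2, 3], "calibration")


class TestOutliers:
    def test_constructed_outlier_flagged(self):
        X, Y = random_instance(14, n=30, p=8, noise=0.05)
        Y = Y.copy()
        Y[7] += 10 * Y.std()
        model = cm.fit_pls(X, Y, 3)
        report = cm.detect_outliers(model, X, Y)
        assert report.flagged[7]
        assert "residual" in report.reasons[7]

    def test_leverage_sums_to_nlv_plus_one(self):
        # hat-matrix trace with the intercept convention
        X, Y = random_instance(15, n=25, p=10)
        model = cm.fit_pls(X, Y, 4)
        report = cm.detect_outliers(model, X, Y)
        assert report.leverage.sum() == pytest.approx(model.n_lv + 1, rel=1e-8)
        assert ((report.leverage >= 0) & (report.leverage <= 1)).all()

    def test_clean_data_rarely_flagged(self):
        n_flags = 0
        n_total = 0
        for seed in range(30):
            X, Y = random_instance(2000 + seed, n=25, p=8, noise=0.1)
            model = cm.fit_pls(X, Y, 3)
            rep = cm.detect_outliers(model, X, Y)
            n_flags += rep.flagged.sum()
            n_total += rep.flagged.size
        assert n_flags / n_total <= 0.05


class TestLod:
    def _blank_model(self, sd, seed=0):
        rng = np.random.default_rng(seed)
        grid = 1800.0 - 4.0 * np.arange(30)
        X = rng.normal(size=(20, 30))
        y = X[:, 0] * 2.0
        model = cm.fit_pls(X, y, 2)
        model.grid = grid
        blanks = rng.normal(size=(12, 30)) * sd
        bset = SpectraSet(grid=grid, matrix=blanks,
                          sample_ids=[f"b{i}" for i in range(12)])
        return model, bset

    def test_zero_noise_blanks(self):
        model, bset = self._blank_model(0.0)
        lod = cm.estimate_lod(model, bset)
        assert lod["y0"] == pytest.approx(0.0, abs=1e-8)

    def test_lod_is_3p3_sigma(self):
        model, bset = self._blank_model(0.5, seed=4)
        preds = cm.predict(model, bset).values[:, 0]
        expected = 3.3 * preds.std(ddof=1)
        assert cm.estimate_lod(model, bset)["y0"] == pytest.approx(expected)

    def test_too_few_blanks(self):
        model, bset = self._blank_model(0.1)
        small = SpectraSet(grid=bset.grid, matrix=bset.matrix[:5],
                           sample_ids=bset.sample_ids[:5])
        with pytest.raises(ValueError, match="too few"):
            cm.estimate_lod(model, small)


class TestSerialization:
    def _fitted_model(self):
        grid = 1800.0 - 4.0 * np.arange(40)
        rng = np.random.default_rng(21)
        matrix = rng.normal(size=(20, 40)) * 0.01 + 0.3
        ref = pd.DataFrame({"t": matrix[:, 5] * 10 + rng.normal(size=20) * 0.01})
        sset = SpectraSet(grid=grid, matrix=matrix,
                          sample_ids=[f"s{i}" for i in range(20)],
                          reference=ref)
        recipe = PreprocessRecipe().add("savgol", window=5, polyorder=2, deriv=0)
        model = cm.calibrate_model(sset, "t", recipe, n_lv=3, unit="mM")
        return model, sset

    def test_round_trip_predictions_identical(self, tmp_path):
        model, sset = self._fitted_model()
        path = tmp_path / "m.json"
        cm.save_model(model, path)
        back = cm.load_model(path)
        np.testing.assert_allclose(cm.predict(back, sset).values,
                                   cm.predict(model, sset).values, atol=1e-12)

    def test_truncated_file_rejected(self, tmp_path):
        model, _ = self._fitted_model()
        path = tmp_path / "m.json"
        cm.save_model(model, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(ValueError, match="corrupt"):
            cm.load_model(path)

    def test_unknown_version_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"schema_version": "bogus-99"}')
        with pytest.raises(ValueError, match="version"):
            cm.load_model(path)


class TestPredictWorkflow:
    def test_water_blank_predicts_zero_after_bias_correction(self, library,
                                                             juice_design,
                                                             noiseless_juice):
        from stalkscreen import synthetic
        recipe = PreprocessRecipe().add("truncate", high=1180, low=900) \
                                   .add("savgol", window=9, polyorder=2, deriv=0)
        model = cm.calibrate_model(noiseless_juice, "sucrose", recipe,
                                   n_lv=6, unit="mM")
        blank_design = synthetic.MixtureDesign(
            table=pd.DataFrame({"sucrose": [0.0], "glucose": [0.0],
                                "fructose": [0.0]}))
        blank = synthetic.simulate_juice_spectra(blank_design, library,
                                                 noise_sd=0.0, seed=0)
        pred = cm.predict(model, blank)
        assert abs(pred.values[0, 0]) < 1e-6

    def test_negative_predictions_flagged_not_clamped(self):
        rng = np.random.default_rng(30)
        grid = 1800.0 - 4.0 * np.arange(20)
        X = rng.normal(size=(15, 20))
        y = X[:, 0]
        model = cm.fit_pls(X, y, 1)
        model.grid = grid
        probe = SpectraSet(grid=grid, matrix=-5 * np.abs(X[:1]),
                           sample_ids=["neg"])
        res = cm.predict(model, probe)
        assert res.negative_flags.any() == (res.values < 0).any()

    def test_missing_wavenumbers_rejected(self, noiseless_juice):
        recipe = PreprocessRecipe().add("savgol", window=9, polyorder=2,
                                        deriv=0)
        model = cm.calibrate_model(noiseless_juice, "sucrose", recipe,
                                   n_lv=6, unit="mM")
        narrow = SpectraSet(grid=noiseless_juice.grid[:50],
                            matrix=noiseless_juice.matrix[:3, :50],
                            sample_ids=["a", "b", "c"])
        with pytest.raises(ValueError):
            cm.predict(model, narrow)
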
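"""Geometric-mean regression, centering, and the macroecological fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ursatroph.diet import default_categories
from ursatroph.inference import MCMCConfig
from ursatroph.macro import (DegenerateRegressionError, InsufficientDataError,
                             MacroModelSpec, build_design, fit_macro,
                             geometric_mean_regression,
                             two_component_centering)
from ursatroph.synthetic import MacroTruth, gen_macro


class TestGeometricMeanRegression:
    def test_identity_line(self):
        v = np.array([0.1, 0.3, 0.6])
        gm = geometric_mean_regression(v, v)
        assert gm.slope == pytest.approx(1.0)
        assert gm.intercept == pytest.approx(0.0, abs=1e-12)

    def test_sd_ratio_example(self):
        logF = np.array([0.0, 1.0, 2.0])
        logV = np.array([0.1, 1.0, 2.3])
        gm = geometric_mean_regression(np.exp(logF), np.exp(logV))
        expect = np.std(logV, ddof=1) / np.std(logF, ddof=1)
        assert gm.slope == pytest.approx(expect)
        assert gm.intercept == pytest.approx(logV.mean() - expect * logF.mean())

    def test_anticorrelated_negative_slope(self):
        f = np.array([0.1, 0.3, 0.6])
        v = np.array([0.6, 0.3, 0.1])
        assert geometric_mean_regression(f, v).slope < 0

    def test_ols_geometric_mean_oracle(self):
        # GM slope equals the signed geometric mean of the two OLS slopes
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.uniform(0.01, 1, 10)
            y = np.exp(0.3 + 1.2 * np.log(x) + rng.normal(0, 0.3, 10))
            gm = geometric_mean_regression(x, y)
            lx, ly = np.log(x), np.log(y)
            b_yx = np.polyfit(lx, ly, 1)[0]
            b_xy = np.polyfit(ly, lx, 1)[0]
            oracle = np.sign(b_yx) * np.sqrt(b_yx / b_xy)
            assert gm.slope == pytest.approx(oracle, abs=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_reciprocity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.01, 1, 8)
        y = rng.uniform(0.01, 1, 8)
        try:
            fwd = geometric_mean_regression(x, y).slope
            rev = geometric_mean_regression(y, x).slope
        except DegenerateRegressionError:
            return
        assert abs(fwd * rev) == pytest.approx(1.0, abs=1e-10)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            geometric_mean_regression([0.5, 0.5], [0.4, 0.6])
        with pytest.raises(DegenerateRegressionError):
            geometric_mean_regression([0.2, 0.2, 0.2], [0.1, 0.3, 0.6])


class TestTwoComponentCentering:
    def test_single_species(self):
        x = np.array([1.0, 2.0, 3.0])
        between, within, _ = two_component_centering(x, ["a"] * 3)
        np.testing.assert_allclose(between, 2.0)
        np.testing.assert_allclose(within, x - 2.0)

    def test_two_species_means(self):
        x = np.array([0.5, 1.5, 2.5, 3.5])
        sp = ["a", "a", "b", "b"]
        between, within, _ = two_component_centering(x, sp)
        np.testing.assert_allclose(between, [1.0, 1.0, 3.0, 3.0])
        np.testing.assert_allclose(between + within, x)
        assert within[:2].sum() == pytest.approx(0.0)

    def test_singleton_species_noted(self):
        _, within, notes = two_component_centering(
            np.array([1.0, 2.0, 5.0]), ["a", "a", "b"])
        assert within[2] == 0.0
        assert notes and "single observation" in notes[0]


class TestFitMacro:
    def test_recovery_without_missing_volumes(self, categories):
        truth = MacroTruth(beta=(-0.5, -0.2, -0.4, -0.3, 0.1),
                           missing_fraction=0.1, n_obs=120, n_studies=90,
                           seed=21)
        datasets, _ = gen_macro(truth)
        fit = fit_macro(datasets, categories,
                        MCMCConfig.reduced(seed=7, chains=2, iterations=1500,
                                           burn_in=400))
        ss = fit.fixed_effect_summaries()
        lo, hi = ss["npp"].eti90
        assert lo <= -0.2 <= hi
        lo, hi = ss["gsl"].eti90
        assert lo <= -0.4 <= hi
        # interval nesting holds for every reported parameter
        for row in fit.summary().itertuples():
            assert row.eti90_lo <= row.eti50_lo <= row.eti50_hi <= row.eti90_hi

    def test_two_component_reconstruction(self, categories, fast_mcmc):
        truth = MacroTruth(n_obs=60, n_studies=40, missing_fraction=0.0,
                           seed=22)
        datasets, _ = gen_macro(truth)
        X, cols = build_design(datasets, MacroModelSpec(two_component=True))
        assert "npp_between" in cols and "npp_within" in cols
        k_b, k_w = cols.index("npp_between"), cols.index("npp_within")
        X1, cols1 = build_design(datasets, MacroModelSpec())
        np.testing.assert_allclose(X[:, k_b] + X[:, k_w],
                                   X1[:, cols1.index("npp")], atol=1e-12)

    def test_requires_observed_volumes(self, categories, fast_mcmc):
        truth = MacroTruth(n_obs=20, n_studies=15, missing_fraction=0.95,
                           seed=23)
        datasets, _ = gen_macro(truth)
        for d in datasets:
            d.items["V"] = np.nan
        with pytest.raises(InsufficientDataError):
            fit_macro(datasets, categories, fast_mcmc)

    def test_diagnostics_shape(self, categories):
        truth = MacroTruth(n_obs=60, n_studies=40, seed=24)
        datasets, _ = gen_macro(truth)
        fit = fit_macro(datasets, categories,
                        MCMCConfig.reduced(seed=9, chains=2, iterations=800,
                                           burn_in=300))
        diag = fit.diagnostics()
        assert 0.0 <= diag.ppp <= 1.0
        assert diag.r2_conditional >= diag.r2_marginal >= 0.0
        assert set(diag.vif) == set(fit.columns[1:])
        pts, line = fit.partial_residuals("npp")
        assert len(pts) == 60 and len(line) == 50
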
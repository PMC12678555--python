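"""Paleoecological sub-models, trophic-position arithmetic, joint fit."""

import copy

import numpy as np
import pandas as pd
import pytest

from ursatroph.inference import MCMCConfig, eti
from ursatroph.paleo import (DegenerateDesignError, InsufficientDataError,
                             fit_elevation_submodel, fit_offset_submodel,
                             fit_paleo, trophic_position)
from ursatroph.synthetic import PaleoTruth, gen_paleo


class TestTrophicPosition:
    @pytest.mark.parametrize("consumer,baseline,tdf,lam,expected", [
        (4.0, 4.0, 3.3, 2.0, 2.0),
        (7.3, 4.0, 3.3, 2.0, 3.0),
        (10.6, 4.0, 3.3, 2.0, 4.0),
    ])
    def test_arithmetic(self, consumer, baseline, tdf, lam, expected):
        assert trophic_position(consumer, baseline, tdf, lam) == \
            pytest.approx(expected)

    def test_affine_in_consumer(self):
        tdf = np.full(100, 3.0)
        c = np.linspace(4, 10, 100)
        tp = trophic_position(c, 4.0, tdf)
        np.testing.assert_allclose(np.diff(tp) / np.diff(c), 1 / 3.0)

    def test_nonpositive_tdf_rejected(self):
        with pytest.raises(ValueError):
            trophic_position(5.0, 4.0, 0.0)


class TestOffsetSubmodel:
    def test_zero_differences_centered_at_zero(self, fast_mcmc):
        post = fit_offset_submodel(np.zeros(20) + 1e-9, fast_mcmc)
        assert abs(np.median(post["mu_T"])) < 0.05

    def test_recovers_offset(self, fast_mcmc):
        rng = np.random.default_rng(31)
        pairs = 0.8 + 0.4 * rng.standard_normal(35)
        post = fit_offset_submodel(pairs, fast_mcmc)
        lo, hi = eti(post["mu_T"], 0.9)
        assert lo <= 0.8 <= hi

    def test_single_pair_rejected(self, fast_mcmc):
        with pytest.raises(InsufficientDataError):
            fit_offset_submodel([0.5], fast_mcmc)


class TestElevationSubmodel:
    def test_recovers_slope(self, fast_mcmc, toy_refs):
        post = fit_elevation_submodel(toy_refs.elevation, fast_mcmc)
        lo, hi = eti(post["beta_E"], 0.9)
        assert lo <= -0.001 <= hi

    def test_single_material_type(self, fast_mcmc):
        rng = np.random.default_rng(32)
        refs = pd.DataFrame({
            "d15N": 4.0 - 0.001 * np.linspace(0, 2000, 25)
            + 0.5 * rng.standard_normal(25),
            "elevation": np.linspace(0, 2000, 25),
            "material": "vegetation"})
        post = fit_elevation_submodel(refs, fast_mcmc)
        assert post["type_intercepts"].shape[-1] == 1

    def test_zero_elevation_range_rejected(self, fast_mcmc):
        refs = pd.DataFrame({"d15N": [1.0, 2.0, 3.0], "elevation": [5.0] * 3,
                             "material": "vegetation"})
        with pytest.raises(DegenerateDesignError):
            fit_elevation_submodel(refs, fast_mcmc)


class TestFitPaleo:
    def test_equal_means_give_tp_two(self):
        truth = PaleoTruth(beta_reg=(2.0, 0.0, 0.0), sigma_TP=1e-6, seed=33)
        samples, refs, env, gt = gen_paleo(truth)
        fit = fit_paleo(samples, refs, env,
                        MCMCConfig.reduced(seed=2, chains=2, iterations=1500,
                                           burn_in=400))
        tp = fit.flat("tp")
        for j in range(tp.shape[1]):
            lo, hi = eti(tp[:, j], 0.9)
            assert lo <= 2.0 <= hi

    def test_shift_equivariance_drawwise(self):
        samples, refs, env, _ = gen_paleo(PaleoTruth(seed=34))
        mcmc = MCMCConfig.reduced(seed=3, chains=1, iterations=600,
                                  burn_in=200)
        fit1 = fit_paleo(samples, refs, env, mcmc)
        shifted = copy.deepcopy(samples)
        for s in shifted:
            s.d15N += 5.0
        fit2 = fit_paleo(shifted, refs, env, mcmc)
        np.testing.assert_allclose(fit2.flat("tp"), fit1.flat("tp"),
                                   rtol=0, atol=1e-8)
        np.testing.assert_allclose(fit2.flat("baseline"),
                                   fit1.flat("baseline") + 5.0, atol=1e-8)

    def test_missing_taxon_period_excluded_from_regression(self, caplog):
        truth = PaleoTruth(n_bear=(10, 10, 10, 10, 10, 10, 10, 0),
                           n_deer=(20, 20, 20, 20, 20, 20, 20, 20), seed=35)
        samples, refs, env, _ = gen_paleo(truth)
        fit = fit_paleo(samples, refs, env,
                        MCMCConfig.reduced(seed=4, chains=1, iterations=600,
                                           burn_in=200))
        assert not fit.identified[-1]
        assert fit.X.shape[0] == 7
        assert np.isnan(fit.flat("tp")[:, -1]).all()
        est = fit.period_estimates()
        assert est[-1].tp is None and est[0].tp is not None

    def test_unassigned_period_rejected(self, fast_mcmc):
        samples, refs, env, _ = gen_paleo(PaleoTruth(seed=36))
        samples[0].period = None
        with pytest.raises(InsufficientDataError, match="period"):
            fit_paleo(samples, refs, env, fast_mcmc)

    def test_joint_vs_modular_agreement(self):
        """Plugging posterior means of the bias terms into a two-stage
        calculation approximates the joint TP medians, and the joint
        intervals are wider (uncertainty propagated)."""
        samples, refs, env, _ = gen_paleo(PaleoTruth(seed=37))
        fit = fit_paleo(samples, refs, env,
                        MCMCConfig.reduced(seed=5, chains=2, iterations=1500,
                                           burn_in=400))
        mu_T = float(np.mean(fit.flat("mu_T")))
        beta_E = float(np.mean(fit.flat("beta_E")))
        mu_D = float(np.mean(fit.flat("mu_Delta")))
        lam = fit.spec.lambda_
        tp_joint = np.median(fit.flat("tp"), axis=0)
        for j, period in enumerate(fit.periods):
            deer = [s for s in samples if s.period == period
                    and s.taxon == "red_deer"]
            bear = [s for s in samples if s.period == period
                    and s.taxon == "brown_bear"]
            base = np.mean([s.d15N - beta_E * s.elevation
                            - mu_T * (s.material == "tooth") for s in deer])
            cons = np.mean([s.d15N - beta_E * s.elevation
                            - mu_T * (s.material == "tooth") for s in bear])
            two_stage = (cons - base) / mu_D + lam
            assert tp_joint[j] == pytest.approx(two_stage, abs=0.25)
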
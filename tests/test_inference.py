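"""Posterior summaries and diagnostics: intervals, pd, PPP, r2, VIF."""

import numpy as np
import pytest

from ursatroph import inference


class TestEti:
    def test_linear_interpolation_rule(self):
        lo, hi = inference.eti(np.arange(1, 101), 0.9)
        assert (lo, hi) == pytest.approx((5.95, 95.05))

    def test_degenerate_constant(self):
        assert inference.eti([3.0, 3.0, 3.0], 0.5) == (3.0, 3.0)

    def test_symmetry(self):
        d = np.concatenate([np.linspace(-2, 2, 401)])
        lo, hi = inference.eti(d, 0.9)
        assert lo == pytest.approx(-hi)

    def test_nesting(self):
        d = np.random.default_rng(0).standard_normal(2000)
        lo50, hi50 = inference.eti(d, 0.5)
        lo90, hi90 = inference.eti(d, 0.9)
        assert lo90 <= lo50 <= hi50 <= hi90

    def test_errors(self):
        with pytest.raises(ValueError):
            inference.eti([], 0.9)
        with pytest.raises(ValueError):
            inference.eti([1, 2], 1.5)


class TestDirectionProbability:
    @pytest.mark.parametrize("draws,expected", [
        ([1, 2, 3], 1.0),
        ([-1, 1, 2, 3], 0.75),
        ([-2, -1, 1, 2], 0.5),
    ])
    def test_examples(self, draws, expected):
        assert inference.direction_probability(draws) == pytest.approx(expected)

    def test_in_half_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.standard_normal(101) + rng.normal(0, 2)
            assert 0.5 <= inference.direction_probability(d) <= 1.0


class TestVif:
    def test_orthogonal_columns(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50, 3))
        q, _ = np.linalg.qr(x - x.mean(0))  # centered, mutually orthogonal
        out = inference.vif(q, ["a", "b", "c"])
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in out.values())

    def test_duplicated_column_infinite(self):
        x = np.random.default_rng(3).standard_normal(30)
        with pytest.warns(UserWarning, match="collinear"):
            out = inference.vif(np.column_stack([x, x]))
        assert np.isinf(out["x0"])

    def test_correlation_061(self):
        # two columns with exact sample correlation 0.61
        rng = np.random.default_rng(4)
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        x2 = 0.61 * a + np.sqrt(1 - 0.61 ** 2) * b
        out = inference.vif(np.column_stack([a, x2]))
        assert out["x0"] == pytest.approx(1 / (1 - 0.61 ** 2), abs=1e-6)
        assert out["x0"] == pytest.approx(1.59, abs=0.005)


class TestR2Mixed:
    def test_limits(self):
        fixed = np.tile(np.linspace(-1, 1, 50), (10, 1))
        r2m, r2c = inference.r2_mixed(fixed, np.zeros((10, 0)),
                                      np.full(10, 1e-12))
        assert np.all(r2m > 0.999)
        r2m, r2c = inference.r2_mixed(np.zeros((10, 50)),
                                      np.full((10, 1), 0.5), np.full(10, 0.5))
        assert np.all(r2m == 0)
        assert np.all(r2c == pytest.approx(0.5))

    def test_known_partition(self):
        var_f = np.var(np.linspace(-1, 1, 1000))
        fixed = np.tile(np.linspace(-1, 1, 1000), (5, 1))
        r2m, r2c = inference.r2_mixed(fixed, np.full((5, 1), 0.2),
                                      np.full(5, 0.3))
        expect_m = var_f / (var_f + 0.2 + 0.3)
        assert r2m == pytest.approx(expect_m, rel=1e-6)
        assert np.all(r2c >= r2m)


class TestPpp:
    def test_gross_misfit_is_extreme(self):
        rng = np.random.default_rng(5)
        mu = np.zeros((200, 30))
        sigma = np.ones(200)
        observed = np.full(30, 10.0)  # +10 sigma shift
        assert inference.ppp_rss(observed, mu, sigma, rng) < 0.01

    def test_self_simulated_is_moderate(self):
        rng = np.random.default_rng(6)
        observed = rng.standard_normal(50)
        mu = np.zeros((500, 50))
        sigma = np.ones(500)
        assert 0.05 < inference.ppp_rss(observed, mu, sigma, rng) < 0.95

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            inference.ppp_rss(np.zeros(3), np.zeros((5, 4)), np.ones(5),
                              np.random.default_rng(0))


class TestPartialResiduals:
    def test_single_predictor_equals_ordinary(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        X = np.column_stack([np.ones(40), x])
        beta = np.array([[0.5, 1.2]] * 100)
        mu = beta @ X.T
        y = 0.5 + 1.2 * x + rng.normal(0, 0.1, 40)
        pts, line = inference.partial_residuals(X, ["intercept", "x"], beta,
                                                y, mu, "x")
        # component + residual = y - intercept for a single-predictor model
        np.testing.assert_allclose(pts["partial_residual"], y - 0.5,
                                   atol=1e-10)
        assert np.all(np.diff(line["median"]) > 0)

    def test_unknown_predictor(self):
        with pytest.raises(KeyError):
            inference.partial_residuals(np.ones((5, 1)), ["intercept"],
                                        np.ones((2, 1)), np.ones(5),
                                        np.ones((2, 5)), "npp")


def test_mcmc_config_bookkeeping():
    cfg = inference.MCMCConfig()
    assert cfg.kept_per_chain == 2000
    assert cfg.total_draws == 10_000
    with pytest.raises(ValueError):
        inference.MCMCConfig(burn_in=-1)


def test_summary_nesting_invariant():
    d = np.random.default_rng(8).standard_normal(500) + 0.3
    s = inference.summarize("x", d)
    assert s.eti90[0] <= s.eti50[0] <= s.median <= s.eti50[1] <= s.eti90[1]
    assert 0.5 <= s.pd <= 1.0
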
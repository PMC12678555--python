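"""Posterior summaries and model diagnostics shared by both hierarchical models.

Conventions, fixed once for the whole package:

* Equal-tailed intervals use linear interpolation of order statistics
  (``numpy.quantile`` default).
* The probability of direction ``pd`` is the fraction of draws sharing the
  sign of the posterior median; draws equal to zero count toward the median's
  sign, so ``pd`` lies in [0.5, 1] up to ties.
* Convergence is flagged when split-R-hat exceeds 1.01.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RHAT_WARN = 1.01


@dataclasses.dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration.

    Defaults mirror the production settings of the analyses (5 chains of
    201,000 iterations, 1,000 burn-in, thinning 100 — 2,000 kept per chain);
    tests and smoke runs use :meth:`reduced`.
    """

    chains: int = 5
    iterations: int = 201_000
    burn_in: int = 1_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 1 or self.thin < 1:
            raise ValueError("chains, iterations and thin must be positive")
        if self.burn_in < 0 or self.burn_in >= self.iterations:
            raise ValueError("burn_in must lie in [0, iterations)")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @property
    def total_draws(self) -> int:
        return self.chains * self.kept_per_chain

    @classmethod
    def reduced(cls, seed: int = 0, chains: int = 2, iterations: int = 2_000,
                burn_in: int = 500, thin: int = 1) -> "MCMCConfig":
        """Short-chain preset for tests and smoke runs."""
        return cls(chains=chains, iterations=iterations, burn_in=burn_in,
                   thin=thin, seed=seed)


@dataclasses.dataclass(frozen=True)
class PosteriorSummary:
    parameter: str
    median: float
    eti50: tuple[float, float]
    eti90: tuple[float, float]
    pd: float

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "median": self.median,
            "eti50_lo": self.eti50[0],
            "eti50_hi": self.eti50[1],
            "eti90_lo": self.eti90[0],
            "eti90_hi": self.eti90[1],
            "pd": self.pd,
        }


@dataclasses.dataclass(frozen=True)
class FitDiagnostics:
    ppp: float
    r2_marginal: float
    r2_conditional: float
    rhat: dict[str, float]
    ess: dict[str, float]
    vif: dict[str, float]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def eti(draws: Sequence[float] | np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval at the given level."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least two draws for an interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def direction_probability(draws: Sequence[float] | np.ndarray) -> float:
    """Fraction of draws sharing the sign of the median (zeros included)."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("need at least one draw")
    med = np.median(draws)
    if med >= 0:
        return float(np.mean(draws >= 0))
    return float(np.mean(draws <= 0))


def summarize(parameter: str, draws: np.ndarray) -> PosteriorSummary:
    draws = np.asarray(draws, dtype=float).ravel()
    return PosteriorSummary(
        parameter=parameter,
        median=float(np.median(draws)),
        eti50=eti(draws, 0.5),
        eti90=eti(draws, 0.9),
        pd=direction_probability(draws),
    )


def summary_table(draws: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Summarize a mapping of parameter name -> draws into one table."""
    rows = [summarize(name, d).as_dict() for name, d in draws.items()]
    return pd.DataFrame(rows)


def ppp_rss(
    observed: np.ndarray,
    mu_draws: np.ndarray,
    sigma_draws: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Posterior predictive p-value comparing residual sums of squares.

    For each posterior draw s, a replicated response is drawn from
    N(mu_s, sigma_s^2) and its RSS about mu_s is compared with the RSS of the
    observed response about mu_s.  Values near 0.5 indicate adequate global
    fit.  With zero residual noise both RSS are zero and ties count as
    "replicate >= observed", giving ppp = 1 by convention.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    mu_draws = np.atleast_2d(np.asarray(mu_draws, dtype=float))
    sigma_draws = np.asarray(sigma_draws, dtype=float).ravel()
    if mu_draws.shape[1] != observed.size or mu_draws.shape[0] != sigma_draws.size:
        raise ValueError("mu_draws must be (n_draws, n_obs) aligned with "
                         "observed and sigma_draws")
    resid = observed[None, :] - mu_draws
    rss_obs = np.sum(resid ** 2, axis=1)
    reps = rng.standard_normal(mu_draws.shape) * sigma_draws[:, None]
    rss_rep = np.sum(reps ** 2, axis=1)
    return float(np.mean(rss_rep >= rss_obs))


def r2_mixed(
    fixed_component_draws: np.ndarray,
    random_variance_draws: np.ndarray,
    residual_variance_draws: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal and conditional variance explained, per posterior draw.

    fixed_component_draws : (n_draws, n_obs) linear predictor from the fixed
        effects only.
    random_variance_draws : (n_draws, n_components) variance of each random
        term (may be empty for a fixed-effects model).
    residual_variance_draws : (n_draws,).
    """
    fixed = np.atleast_2d(np.asarray(fixed_component_draws, dtype=float))
    rand = np.asarray(random_variance_draws, dtype=float)
    if rand.ndim == 1:
        rand = rand[:, None]
    if rand.size == 0:
        rand = np.zeros((fixed.shape[0], 0))
    resid = np.asarray(residual_variance_draws, dtype=float).ravel()
    var_f = np.var(fixed, axis=1)
    var_r = rand.sum(axis=1)
    total = var_f + var_r + resid
    if np.all(total == 0):
        raise ValueError("all variance components are zero")
    r2m = var_f / total
    r2c = (var_f + var_r) / total
    return r2m, r2c


def vif(design: np.ndarray, columns: Sequence[str] | None = None) -> dict[str, float]:
    """Variance inflation factor per design column (intercept excluded upstream).

    VIF_k = 1 / (1 - R^2_k) from regressing column k on the remaining columns
    (with intercept).  Perfect collinearity is reported as ``inf`` with a
    warning rather than an error, so diagnostics never abort a fit.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    n, p = X.shape
    if columns is None:
        columns = [f"x{k}" for k in range(p)]
    out: dict[str, float] = {}
    for k in range(p):
        y = X[:, k]
        others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[columns[k]] = float("nan")
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"column {columns[k]} is perfectly collinear")
            out[columns[k]] = float("inf")
        else:
            out[columns[k]] = float(1.0 / (1.0 - r2))
    return out


def convergence(draws: Mapping[str, np.ndarray]) -> tuple[dict, dict]:
    """Split-R-hat and bulk effective sample size per parameter.

    Each entry must be shaped (chains, kept).  Emits a warning listing the
    parameters whose split-R-hat exceeds the 1.01 threshold.
    """
    import arviz as az

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name, arr in draws.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] == 1:
            # single chain: split it in two so R-hat is still informative
            half = arr.shape[1] // 2
            arr = np.vstack([arr[0, :half], arr[0, half:2 * half]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat[name] = float(az.rhat(arr))
            ess[name] = float(az.ess(arr))
    bad = [k for k, v in rhat.items() if np.isfinite(v) and v > RHAT_WARN]
    if bad:
        warnings.warn(f"split-R-hat > {RHAT_WARN} for: {', '.join(sorted(bad))}")
    return rhat, ess


def partial_residuals(
    X: np.ndarray,
    columns: Sequence[str],
    beta_draws: np.ndarray,
    y: np.ndarray,
    mu_draws: np.ndarray,
    predictor: str,
    grid_size: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Component + residual values and fitted-line draws for one predictor.

    Component ``beta_k * x_k`` is evaluated per draw and summarized; the
    per-observation partial residual is ``y - median full fitted mean +
    median component``.  Other predictors are conditioned at 0, their mean
    after standardization.

    Returns (points, line) data frames: points has one row per observation
    with the observed partial residual; line has one row per grid point with
    the median and 50/90% ETIs of the component.
    """
    columns = list(columns)
    if predictor not in columns:
        raise KeyError(f"unknown predictor {predictor!r}")
    k = columns.index(predictor)
    X = np.asarray(X, dtype=float)
    beta_draws = np.atleast_2d(beta_draws)
    mu_draws = np.atleast_2d(mu_draws)
    comp_draws = beta_draws[:, k][:, None] * X[:, k][None, :]
    comp_med = np.median(comp_draws, axis=0)
    mu_med = np.median(mu_draws, axis=0)
    points = pd.DataFrame({
        predictor: X[:, k],
        "partial_residual": np.asarray(y, dtype=float) - mu_med + comp_med,
    })
    grid = np.linspace(X[:, k].min(), X[:, k].max(), grid_size)
    line_draws = beta_draws[:, k][:, None] * grid[None, :]
    qs = np.quantile(line_draws, [0.05, 0.25, 0.5, 0.75, 0.95], axis=0)
    line = pd.DataFrame({
        predictor: grid,
        "median": qs[2],
        "eti50_lo": qs[1],
        "eti50_hi": qs[3],
        "eti90_lo": qs[0],
        "eti90_hi": qs[4],
    })
    return points, line
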
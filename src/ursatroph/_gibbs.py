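"""Conjugate Gibbs-sampling primitives shared by the two hierarchical models.

All variance parameters carry the weakly informative scaled-inverse-gamma prior
(scale s = 1, df = 2), which puts a half-t(2, 1) prior on the standard
deviation.  The half-t is realized by parameter expansion (Huang & Wand 2013):

    sigma^2 | a ~ InvGamma(nu/2, nu/a),    a ~ InvGamma(1/2, 1/A^2)

marginally gives sigma ~ half-t(nu, A); both conditionals are inverse gamma, so
the expanded model stays fully conjugate.  The 2x2 covariance prior used for
the slope/intercept hierarchy is the matrix analogue: an inverse Wishart mixed
over per-axis auxiliaries, which yields half-t(nu, A) marginal standard
deviations and a marginally uniform correlation — the "scaled inverse Wishart"
with s = 1, df = 2.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

FLAT_VAR = 1.0e4  # variance of the flat normal prior on location parameters


def sample_invgamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    """One draw from InvGamma(shape, rate)."""
    return rate / rng.gamma(shape)


def sample_variance_halft(
    rng: np.random.Generator,
    sse: float,
    n: float,
    a: float,
    nu: float = 2.0,
    A: float = 1.0,
) -> tuple[float, float]:
    """Update (sigma^2, auxiliary a) given a Gaussian sum of squares.

    Parameters
    ----------
    sse : residual sum of squares of the n Gaussian observations.
    a : current value of the expansion auxiliary.
    """
    sigma2 = sample_invgamma(rng, 0.5 * (nu + n), nu / a + 0.5 * sse)
    a_new = sample_invgamma(rng, 0.5 * (nu + 1.0), nu / sigma2 + A ** -2)
    return sigma2, a_new


def sample_cov_halft(
    rng: np.random.Generator,
    devs: np.ndarray,
    a: np.ndarray,
    nu: float = 2.0,
    A: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Update a p x p covariance with half-t(nu, A) SD margins (Huang–Wand).

    devs : (n, p) deviations from the current mean vector.
    a : (p,) expansion auxiliaries.
    """
    n, p = devs.shape
    scale = 2.0 * nu * np.diag(1.0 / a) + devs.T @ devs
    df = nu + p - 1.0 + n
    cov = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    cov = np.atleast_2d(cov)
    prec_diag = np.diag(np.linalg.inv(cov))
    a_new = (nu * prec_diag + A ** -2) / rng.gamma(0.5 * (nu + p), size=p)
    return cov, a_new


def sample_normal_scalar(
    rng: np.random.Generator, precision: float, lin: float
) -> float:
    """Draw from N(lin / precision, 1 / precision)."""
    return lin / precision + rng.standard_normal() / np.sqrt(precision)


def sample_mvn_canonical(
    rng: np.random.Generator, precision: np.ndarray, lin: np.ndarray
) -> np.ndarray:
    """Draw from the MVN with canonical parameters (precision, lin)."""
    chol = np.linalg.cholesky(precision)
    mean = np.linalg.solve(precision, lin)
    z = rng.standard_normal(lin.shape[0])
    return mean + np.linalg.solve(chol.T, z)


def sample_bivariate_batch(
    rng: np.random.Generator,
    prec: np.ndarray,
    lin: np.ndarray,
) -> np.ndarray:
    """Vectorized draws from J bivariate normals in canonical form.

    prec : (J, 2, 2) symmetric positive-definite precisions.
    lin : (J, 2) linear terms; returns (J, 2) draws.
    """
    a = prec[:, 0, 0]
    b = prec[:, 0, 1]
    c = prec[:, 1, 1]
    det = a * c - b * b
    mean0 = (c * lin[:, 0] - b * lin[:, 1]) / det
    mean1 = (a * lin[:, 1] - b * lin[:, 0]) / det
    # Cholesky of the covariance prec^{-1} = [[c, -b], [-b, a]] / det
    c00 = c / det
    c01 = -b / det
    c11 = a / det
    l00 = np.sqrt(c00)
    l10 = c01 / l00
    l11 = np.sqrt(c11 - l10 ** 2)
    z = rng.standard_normal((lin.shape[0], 2))
    out = np.empty_like(lin)
    out[:, 0] = mean0 + l00 * z[:, 0]
    out[:, 1] = mean1 + l10 * z[:, 0] + l11 * z[:, 1]
    return out


def group_normal_effects(
    rng: np.random.Generator,
    resid: np.ndarray,
    index: np.ndarray,
    n_groups: int,
    sigma2_resid: float,
    sigma2_group: float,
) -> np.ndarray:
    """Conjugate update of exchangeable N(0, sigma2_group) group effects.

    resid : partial residuals with every term except this effect removed.
    index : (n,) group index per observation.
    """
    counts = np.bincount(index, minlength=n_groups)
    sums = np.bincount(index, weights=resid, minlength=n_groups)
    prec = counts / sigma2_resid + 1.0 / sigma2_group
    mean = (sums / sigma2_resid) / prec
    return mean + rng.standard_normal(n_groups) / np.sqrt(prec)
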
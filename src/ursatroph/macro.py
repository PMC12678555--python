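"""Macroecological hierarchical model of bear trophic position.

Two coupled sub-models share one posterior:

Sub-model I (imputation).  For datasets reporting both relative frequency of
occurrence (F) and relative volume (V), the per-dataset geometric-mean (GM)
regression of log V on log F is computed deterministically; the pooled GM
intercepts and slopes follow a bivariate normal with mean mu_beta and
covariance Sigma_beta.  For datasets reporting only F, a latent
(intercept, slope) pair is drawn from that distribution and latent log V
values follow

    log V_i ~ Normal(beta_j1 + beta_j2 * log F_i, sigma_V^2).

Imputed volumes are converted to energy contributions and the animal-prey
energy share P, so imputation uncertainty propagates into sub-model II.

Sub-model II (process).  The compressed-probit transform of P is regressed on
log10 NPP, growing season length and co-occurrence dummies with random
intercepts for study and species:

    y_j = probit((P_j (n - 1) + 0.5) / n)
    y_j ~ Normal(sum_k beta_k X_jk + gamma_study + delta_species, sigma_eps^2)

Flat Normal(0, 1e4) priors on all location parameters; half-t(2, 1) priors on
all standard deviations; the "scaled inverse Wishart" (s = 1, df = 2) on
Sigma_beta via its parameter-expanded form.  Sampling is blocked Gibbs; the
only non-conjugate block, the latent log-V vectors (the response transform is
nonlinear in V), mixes by alternating an independence proposal from the
imputation conditional with a random-walk step, both corrected against the
process-model likelihood.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import _gibbs, inference
from ._gibbs import FLAT_VAR
from .diet import (ANIMAL_CLASSES, DietDataset, energy_contribution,
                   probit_compress, validate_categories)


class DegenerateRegressionError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class GMRegression:
    dataset_id: str
    intercept: float  # log-volume units (natural log)
    slope: float


def geometric_mean_regression(
    F: np.ndarray, V: np.ndarray, dataset_id: str = ""
) -> GMRegression:
    """Geometric-mean (standardized major axis) regression of log V on log F.

    slope = sign(cov(logF, logV)) * sqrt(var(logV) / var(logF));
    intercept = mean(logV) - slope * mean(logF).  Only items observed in both
    variables (F > 0 and V > 0) enter; natural logs.
    """
    F = np.asarray(F, dtype=float)
    V = np.asarray(V, dtype=float)
    mask = (F > 0) & (V > 0) & np.isfinite(F) & np.isfinite(V)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"{dataset_id or 'GMR'}: need >= 3 paired positive items, "
            f"got {int(mask.sum())}")
    x = np.log(F[mask])
    y = np.log(V[mask])
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateRegressionError(
            f"{dataset_id or 'GMR'}: zero variance in log F or log V")
    cov = np.cov(x, y, ddof=1)[0, 1]
    sign = 1.0 if cov >= 0 else -1.0  # cov == 0 tie-break: positive
    slope = sign * np.sqrt(vy / vx)
    intercept = y.mean() - slope * x.mean()
    return GMRegression(dataset_id=dataset_id, intercept=float(intercept),
                        slope=float(slope))


def two_component_centering(
    values: np.ndarray, species: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a predictor into species means (between) and deviations (within).

    Returns (between, within, notes); deviations sum to zero within each
    species, and between + within reconstructs the input exactly.  Species
    with a single observation get deviation 0 and are noted.
    """
    values = np.asarray(values, dtype=float)
    species = np.asarray(species)
    between = np.empty_like(values)
    notes: list[str] = []
    for sp in pd.unique(species):
        idx = species == sp
        between[idx] = values[idx].mean()
        if idx.sum() == 1:
            notes.append(f"species {sp} has a single observation; "
                         "within-species deviation is 0")
    return between, values - between, notes


@dataclasses.dataclass(frozen=True)
class MacroModelSpec:
    """Model configuration for the macroecological fit.

    compress_n: the n of the probit compression; defaults to the number of
    trophic-position observations.  standardize: z-score log10(npp) and gsl
    before fitting (coefficients are then per-SD effects, the convention used
    for the partial-residual displays).  two_component: replace each
    environmental predictor by its species-mean (occurrence) and
    within-species (population) components.
    """

    standardize: bool = True
    two_component: bool = False
    compress_n: int | None = None
    reference_co_occurrence: str = "none"
    rw_step: float = 0.2  # random-walk scale for the latent log-V block


@dataclasses.dataclass
class MacroFit:
    draws: dict[str, np.ndarray]  # (chains, kept[, dim])
    columns: list[str]
    X: np.ndarray
    y: np.ndarray  # observed y where available, posterior-median y where imputed
    observed_mask: np.ndarray
    compress_n: int
    gm_pool: list[GMRegression]
    accept_rates: dict[str, float]
    spec: MacroModelSpec
    mcmc: inference.MCMCConfig

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled across chains; shape (total, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def beta_draws(self) -> np.ndarray:
        return self.flat("beta")

    def fixed_effect_summaries(self) -> dict[str, inference.PosteriorSummary]:
        b = self.beta_draws()
        return {c: inference.summarize(c, b[:, k])
                for k, c in enumerate(self.columns)}

    def summary(self) -> pd.DataFrame:
        params: dict[str, np.ndarray] = {}
        b = self.beta_draws()
        for k, c in enumerate(self.columns):
            params[f"beta[{c}]"] = b[:, k]
        for name in ("sigma_eps", "sigma_gamma", "sigma_delta", "sigma_V",
                     "sigma_b1", "sigma_b2", "rho_beta"):
            params[name] = self.flat(name)
        mu = self.flat("mu_beta")
        params["mu_beta[intercept]"] = mu[:, 0]
        params["mu_beta[slope]"] = mu[:, 1]
        return inference.summary_table(params)

    def imputed_P(self) -> pd.DataFrame:
        """Posterior median and 90% ETI of the animal-prey energy share P_j."""
        P = self.flat("P")
        qs = np.quantile(P, [0.05, 0.5, 0.95], axis=0)
        return pd.DataFrame({"median": qs[1], "eti90_lo": qs[0],
                             "eti90_hi": qs[2],
                             "observed": self.observed_mask})

    def diagnostics(self, rng: np.random.Generator | None = None
                    ) -> inference.FitDiagnostics:
        rng = rng or np.random.default_rng(self.mcmc.seed + 1)
        obs = self.observed_mask
        mu = self.flat("mu")
        sig = np.sqrt(self.flat("sigma_eps2"))
        ppp = inference.ppp_rss(self.y[obs], mu[:, obs], sig, rng)
        fixed = self.beta_draws() @ self.X.T
        rand = np.column_stack([self.flat("sigma_gamma2"),
                                self.flat("sigma_delta2")])
        r2m, r2c = inference.r2_mixed(fixed, rand, self.flat("sigma_eps2"))
        conv_params = {f"beta[{c}]": self.draws["beta"][:, :, k]
                       for k, c in enumerate(self.columns)}
        for name in ("sigma_eps", "sigma_gamma", "sigma_delta", "sigma_V"):
            conv_params[name] = self.draws[name]
        rhat, ess = inference.convergence(conv_params)
        vifs = inference.vif(self.X[:, 1:], self.columns[1:])
        return inference.FitDiagnostics(
            ppp=ppp, r2_marginal=float(np.median(r2m)),
            r2_conditional=float(np.median(r2c)), rhat=rhat, ess=ess,
            vif=vifs)

    def partial_residuals(self, predictor: str):
        return inference.partial_residuals(
            self.X, self.columns, self.beta_draws(), self.y,
            self.flat("mu"), predictor)


def build_design(
    datasets: Sequence[DietDataset], spec: MacroModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, environmental predictors, co-occurrence dummies."""
    npp = np.log10([d.npp for d in datasets])
    gsl = np.array([float(d.gsl) for d in datasets])
    species = [d.species for d in datasets]
    if spec.standardize:
        npp = (npp - npp.mean()) / npp.std(ddof=1)
        gsl = (gsl - gsl.mean()) / gsl.std(ddof=1)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(datasets)))]
    if spec.two_component:
        for name, v in (("npp", npp), ("gsl", gsl)):
            bet, wit, notes = two_component_centering(v, species)
            for note in notes:
                warnings.warn(note)
            cols.append((f"{name}_between", bet))
            cols.append((f"{name}_within", wit))
    else:
        cols.append(("npp", npp))
        cols.append(("gsl", gsl))
    levels = [lv for lv in ("none", "subordinate", "dominant")
              if lv != spec.reference_co_occurrence]
    co = np.array([d.co_occurrence for d in datasets])
    for lv in levels:
        if np.any(co == lv):
            cols.append((f"co_{lv}", (co == lv).astype(float)))
    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return X, names


def _prepare(datasets: Sequence[DietDataset], categories: pd.DataFrame):
    """Split datasets into observed-V and imputation groups; pad item arrays."""
    validate_categories(categories)
    n = len(datasets)
    obs_mask = np.array([not d.needs_imputation for d in datasets])
    P_obs = np.full(n, np.nan)
    gm_pool: list[GMRegression] = []
    sse_c = 0.0
    n_c = 0
    for j, d in enumerate(datasets):
        if not obs_mask[j]:
            continue
        v = d.items["V"]
        P_obs[j] = energy_contribution(v, categories, d.dataset_id).P
        f = d.items["F"].to_numpy(dtype=float)
        vv = v.to_numpy(dtype=float)
        try:
            gm = geometric_mean_regression(f, vv, d.dataset_id)
        except (InsufficientDataError, DegenerateRegressionError):
            continue
        gm_pool.append(gm)
        m = (f > 0) & (vv > 0)
        resid = np.log(vv[m]) - gm.intercept - gm.slope * np.log(f[m])
        sse_c += float(resid @ resid)
        n_c += int(m.sum())
    mis_idx = np.flatnonzero(~obs_mask)
    imax = 1
    for j in mis_idx:
        imax = max(imax, int((datasets[j].items["F"] > 0).sum()))
    M = len(mis_idx)
    logF = np.zeros((M, imax))
    mask = np.zeros((M, imax), dtype=bool)
    w = np.zeros((M, imax))
    animal = np.zeros((M, imax), dtype=bool)
    for r, j in enumerate(mis_idx):
        items = datasets[j].items
        pos = items[items["F"] > 0]
        cats = categories.loc[pos.index]
        k = len(pos)
        logF[r, :k] = np.log(pos["F"].to_numpy(dtype=float))
        mask[r, :k] = True
        w[r, :k] = cats["c_D"].to_numpy() * cats["c_E"].to_numpy()
        animal[r, :k] = cats["trophic_class"].isin(ANIMAL_CLASSES).to_numpy()
    return obs_mask, P_obs, gm_pool, sse_c, n_c, mis_idx, logF, mask, w, animal


def _share_from_logV(logV, mask, w, animal):
    """Animal-prey energy share per imputation dataset, scale-stabilized."""
    shifted = logV - np.where(mask, logV, -np.inf).max(axis=1, keepdims=True)
    ev = np.where(mask, np.exp(shifted), 0.0)
    tot = (w * ev).sum(axis=1)
    ani = (w * ev * animal).sum(axis=1)
    return ani / tot


def fit_macro(
    datasets: Sequence[DietDataset],
    categories: pd.DataFrame,
    mcmc: inference.MCMCConfig,
    spec: MacroModelSpec = MacroModelSpec(),
) -> MacroFit:
    """Fit the joint imputation + process model by blocked Gibbs sampling."""
    n = len(datasets)
    if n < 2:
        raise InsufficientDataError("need at least two datasets")
    (obs_mask, P_obs, gm_pool, sse_c, n_c, mis_idx, logF, mask, w,
     animal) = _prepare(datasets, categories)
    if not gm_pool:
        raise InsufficientDataError(
            "no dataset with observed V supports the slope/intercept hierarchy")
    X, columns = build_design(datasets, spec)
    p = X.shape[1]
    n_compress = spec.compress_n or n
    y_obs = np.full(n, np.nan)
    y_obs[obs_mask] = probit_compress(P_obs[obs_mask], n_compress)

    study_ids = pd.Categorical([d.study_id for d in datasets])
    species_ids = pd.Categorical([d.species for d in datasets])
    study = np.asarray(study_ids.codes, dtype=int)
    species = np.asarray(species_ids.codes, dtype=int)
    n_study = len(study_ids.categories)
    n_species = len(species_ids.categories)

    gm_obs = np.array([[g.intercept, g.slope] for g in gm_pool])
    M = len(mis_idx)
    item_counts = mask.sum(axis=1)
    n_items_mis = int(item_counts.sum())

    kept = mcmc.kept_per_chain
    store = {
        "beta": np.empty((mcmc.chains, kept, p)),
        "mu": np.empty((mcmc.chains, kept, n)),
        "P": np.empty((mcmc.chains, kept, n)),
        "mu_beta": np.empty((mcmc.chains, kept, 2)),
        "sigma_eps2": np.empty((mcmc.chains, kept)),
        "sigma_gamma2": np.empty((mcmc.chains, kept)),
        "sigma_delta2": np.empty((mcmc.chains, kept)),
        "sigma_V": np.empty((mcmc.chains, kept)),
        "sigma_b1": np.empty((mcmc.chains, kept)),
        "sigma_b2": np.empty((mcmc.chains, kept)),
        "rho_beta": np.empty((mcmc.chains, kept)),
    }
    acc_ind = acc_rw = prop_ind = prop_rw = 0.0
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)

    # precomputed per-dataset sums for the latent (intercept, slope) update
    s0 = item_counts.astype(float)
    s1 = (logF * mask).sum(axis=1)
    s2 = (logF ** 2 * mask).sum(axis=1)

    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        # -- initialization from the observed pool --
        mu_beta = gm_obs.mean(axis=0)
        Sigma_beta = np.cov(gm_obs.T) + 1e-3 * np.eye(2)
        beta_mis = np.tile(mu_beta, (M, 1))
        logV = beta_mis[:, [0]] + beta_mis[:, [1]] * logF
        sigma_V2 = max(sse_c / max(n_c, 1), 1e-3)
        y = y_obs.copy()
        if M:
            y[mis_idx] = probit_compress(
                np.clip(_share_from_logV(logV, mask, w, animal), 0, 1), n_compress)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        gamma = np.zeros(n_study)
        delta = np.zeros(n_species)
        sigma_eps2 = max(float(np.var(y - X @ beta)), 1e-3)
        sigma_gamma2 = sigma_delta2 = 0.25
        a_eps = a_gam = a_del = a_V = 1.0
        a_Sig = np.ones(2)

        for it in range(mcmc.iterations):
            # --- sub-model I: latent (intercept, slope) per imputation dataset
            if M:
                Sinv = np.linalg.inv(Sigma_beta)
                t0 = (logV * mask).sum(axis=1)
                t1 = (logV * logF * mask).sum(axis=1)
                prec = np.empty((M, 2, 2))
                prec[:, 0, 0] = Sinv[0, 0] + s0 / sigma_V2
                prec[:, 0, 1] = prec[:, 1, 0] = Sinv[0, 1] + s1 / sigma_V2
                prec[:, 1, 1] = Sinv[1, 1] + s2 / sigma_V2
                lin = (Sinv @ mu_beta)[None, :] + \
                    np.column_stack([t0, t1]) / sigma_V2
                beta_mis = _gibbs.sample_bivariate_batch(rng, prec, lin)

                # --- latent log V: independence + random-walk MH, vectorized
                mu_impute = beta_mis[:, [0]] + beta_mis[:, [1]] * logF
                mu_reg = X @ beta + gamma[study] + delta[species]
                mu_reg_mis = mu_reg[mis_idx]
                y_mis = y[mis_idx]

                for move in ("ind", "rw"):
                    if move == "ind":
                        cand = mu_impute + \
                            np.sqrt(sigma_V2) * rng.standard_normal(logV.shape)
                        extra = np.zeros(M)
                    else:
                        cand = logV + spec.rw_step * rng.standard_normal(logV.shape)
                        d_new = ((cand - mu_impute) ** 2 * mask).sum(axis=1)
                        d_old = ((logV - mu_impute) ** 2 * mask).sum(axis=1)
                        extra = -(d_new - d_old) / (2 * sigma_V2)
                    P_cand = np.clip(_share_from_logV(cand, mask, w, animal), 0, 1)
                    y_cand = probit_compress(P_cand, n_compress)
                    logr = extra - ((y_cand - mu_reg_mis) ** 2
                                    - (y_mis - mu_reg_mis) ** 2) / (2 * sigma_eps2)
                    accept = np.log(rng.random(M)) < logr
                    logV = np.where(accept[:, None], cand, logV)
                    y_mis = np.where(accept, y_cand, y_mis)
                    if it >= mcmc.burn_in:
                        if move == "ind":
                            prop_ind += M
                            acc_ind += accept.sum()
                        else:
                            prop_rw += M
                            acc_rw += accept.sum()
                y[mis_idx] = y_mis

            # --- hierarchy over GM coefficients
            all_beta = np.vstack([gm_obs, beta_mis]) if M else gm_obs
            nb = all_beta.shape[0]
            Sinv = np.linalg.inv(Sigma_beta)
            prec_mu = nb * Sinv + np.eye(2) / FLAT_VAR
            lin_mu = Sinv @ all_beta.sum(axis=0)
            mu_beta = _gibbs.sample_mvn_canonical(rng, prec_mu, lin_mu)
            Sigma_beta, a_Sig = _gibbs.sample_cov_halft(
                rng, all_beta - mu_beta, a_Sig)

            # --- residual variance of the imputation regression
            if M:
                mu_impute = beta_mis[:, [0]] + beta_mis[:, [1]] * logF
                sse_m = float((((logV - mu_impute) ** 2) * mask).sum())
            else:
                sse_m = 0.0
            sigma_V2, a_V = _gibbs.sample_variance_halft(
                rng, sse_c + sse_m, n_c + n_items_mis, a_V)

            # --- sub-model II: mixed-effects regression on the probit scale
            resid = y - gamma[study] - delta[species]
            prec_b = X.T @ X / sigma_eps2 + np.eye(p) / FLAT_VAR
            lin_b = X.T @ resid / sigma_eps2
            beta = _gibbs.sample_mvn_canonical(rng, prec_b, lin_b)
            fixed = X @ beta
            gamma = _gibbs.group_normal_effects(
                rng, y - fixed - delta[species], study, n_study,
                sigma_eps2, sigma_gamma2)
            delta = _gibbs.group_normal_effects(
                rng, y - fixed - gamma[study], species, n_species,
                sigma_eps2, sigma_delta2)
            mu_full = fixed + gamma[study] + delta[species]
            err = y - mu_full
            sigma_eps2, a_eps = _gibbs.sample_variance_halft(
                rng, float(err @ err), n, a_eps)
            sigma_gamma2, a_gam = _gibbs.sample_variance_halft(
                rng, float(gamma @ gamma), n_study, a_gam)
            sigma_delta2, a_del = _gibbs.sample_variance_halft(
                rng, float(delta @ delta), n_species, a_del)

            # --- store
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                k = (it - mcmc.burn_in) // mcmc.thin
                if k < kept:
                    store["beta"][c, k] = beta
                    store["mu"][c, k] = mu_full
                    Pvec = P_obs.copy()
                    if M:
                        Pvec[mis_idx] = np.clip(
                            _share_from_logV(logV, mask, w, animal), 0, 1)
                    store["P"][c, k] = Pvec
                    store["mu_beta"][c, k] = mu_beta
                    store["sigma_eps2"][c, k] = sigma_eps2
                    store["sigma_gamma2"][c, k] = sigma_gamma2
                    store["sigma_delta2"][c, k] = sigma_delta2
                    store["sigma_V"][c, k] = np.sqrt(sigma_V2)
                    store["sigma_b1"][c, k] = np.sqrt(Sigma_beta[0, 0])
                    store["sigma_b2"][c, k] = np.sqrt(Sigma_beta[1, 1])
                    store["rho_beta"][c, k] = Sigma_beta[0, 1] / np.sqrt(
                        Sigma_beta[0, 0] * Sigma_beta[1, 1])

    for name in ("sigma_eps", "sigma_gamma", "sigma_delta"):
        store[name] = np.sqrt(store[name + "2"])
    y_final = y_obs.copy()
    if M:
        P_med = np.median(store["P"].reshape(-1, n), axis=0)
        y_final[mis_idx] = probit_compress(
            np.clip(P_med[mis_idx], 0, 1), n_compress)
    rates = {"independence": acc_ind / prop_ind if prop_ind else float("nan"),
             "random_walk": acc_rw / prop_rw if prop_rw else float("nan")}
    return MacroFit(draws=store, columns=columns, X=X, y=y_final,
                    observed_mask=obs_mask, compress_n=n_compress,
                    gm_pool=gm_pool, accept_rates=rates, spec=spec, mcmc=mcmc)
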
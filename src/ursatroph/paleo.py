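"""Paleoecological hierarchical model: brown-bear trophic position over 55 ka.

One joint posterior couples five Gaussian sub-models:

* tooth-bone offset mu_T from paired tooth/bone differences;
* elevation effect beta_E (shared slope, material-type intercepts) from
  reference d15N data of plants and herbivore tissues;
* per-period bias-corrected means for red deer (baseline_j) and brown bear
  (consumer_j), where each observation's mean is
  ``period mean + beta_E * elevation + mu_T * is_tooth`` — so the period
  means are bone-equivalent, elevation-zero quantities;
* trophic discrimination factor mu_Delta from predator-prey pairs;
* the period-level regression of trophic position

      TP_j = (consumer_j - baseline_j) / mu_Delta + lambda
      TP_j ~ Normal(X_j beta, sigma_TP^2)

  on standardized log10 NPP and growing season length, with lambda = 2 the
  trophic level of the herbivore baseline.

All location priors are Normal(0, 1e4); all variances carry the
scaled-inverse-gamma (s = 1, df = 2) prior, i.e. half-t(2, 1) standard
deviations.  Every conditional is conjugate except mu_Delta, which enters the
regression through 1/mu_Delta and is updated by an independence
Metropolis-Hastings step proposing from its conjugate conditional given the
discrimination pairs (proposals <= 0 are rejected, keeping the TDF positive).

Periods where either taxon is absent have a non-identified trophic position;
they are excluded from the regression and flagged in the output.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import _gibbs, inference
from ._gibbs import FLAT_VAR
from .isotopes import PERIOD_NAMES, IsotopeSample, ReferenceTables

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PaleoModelSpec:
    lambda_: float = 2.0  # trophic level of the baseline herbivore
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be > 0")


@dataclasses.dataclass(frozen=True)
class PeriodEstimate:
    period: str
    baseline: inference.PosteriorSummary
    consumer: inference.PosteriorSummary
    tp: inference.PosteriorSummary | None  # None when non-identified
    n_bear: int
    n_deer: int

    @property
    def identified(self) -> bool:
        return self.tp is not None


def trophic_position(
    consumer: np.ndarray | float,
    baseline: np.ndarray | float,
    tdf: np.ndarray | float,
    lambda_: float = 2.0,
) -> np.ndarray | float:
    """TP = (consumer - baseline) / tdf + lambda, applied drawwise."""
    tdf_arr = np.asarray(tdf, dtype=float)
    if np.any(tdf_arr <= 0):
        raise ValueError("trophic discrimination factor must be > 0")
    out = (np.asarray(consumer, float) - np.asarray(baseline, float)) / tdf_arr \
        + lambda_
    return float(out) if np.isscalar(consumer) and np.isscalar(tdf) else out


def _normal_mean_gibbs(rng, data, n_iter, burn, thin, chains, seed_offset=0):
    """Mini Gibbs for the exchangeable-normal model (mean + variance)."""
    data = np.asarray(data, dtype=float)
    n = data.size
    kept = (n_iter - burn) // thin
    mu_out = np.empty((chains, kept))
    s2_out = np.empty((chains, kept))
    seeds = rng.spawn(chains) if hasattr(rng, "spawn") else None
    for c in range(chains):
        r = np.random.default_rng(seeds[c]) if seeds else rng
        mu = float(data.mean())
        s2 = float(max(data.var(), 1e-6))
        a = 1.0
        for it in range(n_iter):
            prec = n / s2 + 1.0 / FLAT_VAR
            mu = _gibbs.sample_normal_scalar(r, prec, data.sum() / s2)
            sse = float(((data - mu) ** 2).sum())
            s2, a = _gibbs.sample_variance_halft(r, sse, n, a)
            if it >= burn and (it - burn) % thin == 0:
                k = (it - burn) // thin
                if k < kept:
                    mu_out[c, k] = mu
                    s2_out[c, k] = s2
    return mu_out, s2_out


def fit_offset_submodel(
    pairs: np.ndarray, mcmc: inference.MCMCConfig
) -> dict[str, np.ndarray]:
    """Posterior of the tooth-bone offset (mu_T, sigma_T^2) on its own."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size < 2:
        raise InsufficientDataError("need >= 2 tooth-bone pairs")
    rng = np.random.SeedSequence(mcmc.seed)
    mu, s2 = _normal_mean_gibbs(rng, pairs, mcmc.iterations, mcmc.burn_in,
                                mcmc.thin, mcmc.chains)
    return {"mu_T": mu, "sigma_T2": s2}


def fit_elevation_submodel(
    refs: pd.DataFrame, mcmc: inference.MCMCConfig
) -> dict[str, np.ndarray]:
    """Posterior of the elevation slope and material-type intercepts on their own."""
    if len(refs) < 3:
        raise InsufficientDataError("need >= 3 elevation reference observations")
    elev = refs["elevation"].to_numpy(dtype=float)
    if np.ptp(elev) == 0:
        raise DegenerateDesignError("zero elevation range in reference data")
    d15n = refs["d15N"].to_numpy(dtype=float)
    types = pd.Categorical(refs["material"])
    tcode = np.asarray(types.codes, dtype=int)
    n_types = len(types.categories)
    kept = mcmc.kept_per_chain
    beta_out = np.empty((mcmc.chains, kept))
    type_out = np.empty((mcmc.chains, kept, n_types))
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        inter = np.array([d15n[tcode == t].mean() for t in range(n_types)])
        beta_E = 0.0
        s2 = float(max(d15n.var(), 1e-6))
        a = 1.0
        for it in range(mcmc.iterations):
            resid = d15n - beta_E * elev
            for t in range(n_types):
                m = tcode == t
                prec = m.sum() / s2 + 1.0 / FLAT_VAR
                inter[t] = _gibbs.sample_normal_scalar(
                    rng, prec, resid[m].sum() / s2)
            resid = d15n - inter[tcode]
            prec = (elev @ elev) / s2 + 1.0 / FLAT_VAR
            beta_E = _gibbs.sample_normal_scalar(rng, prec, (elev @ resid) / s2)
            err = resid - beta_E * elev
            s2, a = _gibbs.sample_variance_halft(rng, float(err @ err),
                                                 d15n.size, a)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                k = (it - mcmc.burn_in) // mcmc.thin
                if k < kept:
                    beta_out[c, k] = beta_E
                    type_out[c, k] = inter
    return {"beta_E": beta_out, "type_intercepts": type_out,
            "types": list(types.categories)}


@dataclasses.dataclass
class PaleoFit:
    draws: dict[str, np.ndarray]
    periods: list[str]
    identified: np.ndarray
    reg_columns: list[str]
    X: np.ndarray  # period-level design (identified periods only)
    n_bear: np.ndarray
    n_deer: np.ndarray
    spec: PaleoModelSpec
    mcmc: inference.MCMCConfig
    accept_rate_tdf: float
    observed: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def period_estimates(self) -> list[PeriodEstimate]:
        base = self.flat("baseline")
        cons = self.flat("consumer")
        tp = self.flat("tp")
        out = []
        for j, name in enumerate(self.periods):
            out.append(PeriodEstimate(
                period=name,
                baseline=inference.summarize(f"baseline[{name}]", base[:, j]),
                consumer=inference.summarize(f"consumer[{name}]", cons[:, j]),
                tp=(inference.summarize(f"tp[{name}]", tp[:, j])
                    if self.identified[j] else None),
                n_bear=int(self.n_bear[j]), n_deer=int(self.n_deer[j])))
        return out

    def tp_table(self) -> pd.DataFrame:
        rows = []
        for est in self.period_estimates():
            row = {"period": est.period, "n_bear": est.n_bear,
                   "n_deer": est.n_deer, "identified": est.identified}
            if est.tp is not None:
                row.update({k: v for k, v in est.tp.as_dict().items()
                            if k != "parameter"})
            rows.append(row)
        return pd.DataFrame(rows)

    def regression_summaries(self) -> dict[str, inference.PosteriorSummary]:
        b = self.flat("beta_reg")
        return {c: inference.summarize(c, b[:, k])
                for k, c in enumerate(self.reg_columns)}

    def summary(self) -> pd.DataFrame:
        params: dict[str, np.ndarray] = {}
        for k, c in enumerate(self.reg_columns):
            params[f"beta_reg[{c}]"] = self.flat("beta_reg")[:, k]
        for name in ("mu_T", "beta_E", "mu_Delta", "sigma_TP"):
            params[name] = self.flat(name)
        for j, p in enumerate(self.periods):
            if self.identified[j]:
                params[f"tp[{p}]"] = self.flat("tp")[:, j]
        return inference.summary_table(params)

    def convergence(self) -> tuple[dict, dict]:
        conv = {f"beta_reg[{c}]": self.draws["beta_reg"][:, :, k]
                for k, c in enumerate(self.reg_columns)}
        for name in ("mu_T", "beta_E", "mu_Delta", "sigma_TP"):
            conv[name] = self.draws[name]
        return inference.convergence(conv)


def build_period_design(
    env: pd.DataFrame, periods: Sequence[str], spec: PaleoModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Intercept + (standardized) log10 NPP and GSL for the given periods."""
    env = env.set_index("period").loc[list(periods)]
    npp = np.log10(env["npp"].to_numpy(dtype=float))
    gsl = env["gsl"].to_numpy(dtype=float)
    if spec.standardize:
        npp = (npp - npp.mean()) / npp.std(ddof=1)
        gsl = (gsl - gsl.mean()) / gsl.std(ddof=1)
    X = np.column_stack([np.ones(len(periods)), npp, gsl])
    return X, ["intercept", "npp", "gsl"]


def fit_paleo(
    samples: Sequence[IsotopeSample],
    refs: ReferenceTables,
    env: pd.DataFrame,
    mcmc: inference.MCMCConfig,
    spec: PaleoModelSpec = PaleoModelSpec(),
    periods: Sequence[str] = PERIOD_NAMES,
) -> PaleoFit:
    """Fit the joint paleoecological model by blocked Gibbs sampling."""
    refs.validate()
    lam = spec.lambda_
    periods = list(periods)
    pindex = {p: j for j, p in enumerate(periods)}
    unassigned = [s.sample_id for s in samples if s.period is None]
    if unassigned:
        raise InsufficientDataError(
            f"{len(unassigned)} samples lack a period (e.g. {unassigned[:3]}); "
            "assign periods (and drop gap-age samples) before fitting")

    def arrays(taxon):
        sel = [s for s in samples if s.taxon == taxon]
        val = np.array([s.d15N for s in sel])
        elev = np.array([s.elevation for s in sel])
        tooth = np.array([1.0 if s.material == "tooth" else 0.0 for s in sel])
        per = np.array([pindex[s.period] for s in sel], dtype=int)
        return val, elev, tooth, per

    B, eB, tB, pB = arrays("red_deer")  # baseline
    C, eC, tC, pC = arrays("brown_bear")  # consumer
    # Center the response internally so the sampler (and hence TP) is exactly
    # equivariant under a common shift of all d15N values; the flat prior on
    # the period means is thereby anchored at the grand mean, which with
    # variance 1e4 is immaterial.  The center is added back on storage.
    center = float(np.mean(np.concatenate([B, C])))
    B = B - center
    C = C - center
    nJ = len(periods)
    n_deer = np.bincount(pB, minlength=nJ)
    n_bear = np.bincount(pC, minlength=nJ)
    identified = (n_deer > 0) & (n_bear > 0)
    if identified.sum() < 2:
        raise InsufficientDataError(
            "need both taxa present in at least two periods")
    for j, p in enumerate(periods):
        if not identified[j]:
            logger.warning(
                "period %s non-identified (bears=%d, deer=%d); excluded from "
                "the regression", p, n_bear[j], n_deer[j])

    T = np.asarray(refs.tooth_bone, dtype=float)
    D = np.asarray(refs.tdf, dtype=float)
    elev_refs = refs.elevation
    N = elev_refs["d15N"].to_numpy(dtype=float)
    eN = elev_refs["elevation"].to_numpy(dtype=float)
    if np.ptp(eN) == 0:
        raise DegenerateDesignError("zero elevation range in reference data")
    types = pd.Categorical(elev_refs["material"])
    tN = np.asarray(types.codes, dtype=int)
    n_types = len(types.categories)

    Xid, reg_columns = build_period_design(env, [p for j, p in enumerate(periods)
                                                 if identified[j]], spec)
    id_idx = np.flatnonzero(identified)
    preg = Xid.shape[1]

    kept = mcmc.kept_per_chain
    store = {
        "baseline": np.empty((mcmc.chains, kept, nJ)),
        "consumer": np.empty((mcmc.chains, kept, nJ)),
        "tp": np.full((mcmc.chains, kept, nJ), np.nan),
        "beta_reg": np.empty((mcmc.chains, kept, preg)),
        "mu_T": np.empty((mcmc.chains, kept)),
        "beta_E": np.empty((mcmc.chains, kept)),
        "mu_Delta": np.empty((mcmc.chains, kept)),
        "type_intercepts": np.empty((mcmc.chains, kept, n_types)),
        "sigma_B2": np.empty((mcmc.chains, kept)),
        "sigma_C2": np.empty((mcmc.chains, kept)),
        "sigma_TP": np.empty((mcmc.chains, kept)),
        "mu_B": np.empty((mcmc.chains, kept, B.size)),
        "mu_C": np.empty((mcmc.chains, kept, C.size)),
    }
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    acc = prop = 0.0

    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        # shift-equivariant initialization from per-period sample means
        baseline = np.array([B[pB == j].mean() if n_deer[j] else 0.0
                             for j in range(nJ)])
        consumer = np.array([C[pC == j].mean() if n_bear[j] else 0.0
                             for j in range(nJ)])
        mu_T = float(T.mean())
        mu_D = float(D.mean())
        beta_E = 0.0
        inter = np.array([N[tN == t].mean() for t in range(n_types)])
        s2_T = float(max(T.var(), 1e-6))
        s2_N = float(max(N.var(), 1e-6))
        s2_B = float(max(B.var(), 1e-6))
        s2_C = float(max(C.var(), 1e-6))
        s2_D = float(max(D.var(), 1e-6))
        s2_TP = 0.25
        beta_reg = np.zeros(preg)
        a_T = a_N = a_B = a_C = a_D = a_TP = 1.0

        for it in range(mcmc.iterations):
            # --- material-type intercepts (reference data only)
            residN = N - beta_E * eN
            for t in range(n_types):
                m = tN == t
                prec = m.sum() / s2_N + 1.0 / FLAT_VAR
                inter[t] = _gibbs.sample_normal_scalar(
                    rng, prec, residN[m].sum() / s2_N)

            # --- shared elevation slope: refs + deer + bear likelihoods
            rN = N - inter[tN]
            rB = B - baseline[pB] - mu_T * tB
            rC = C - consumer[pC] - mu_T * tC
            prec = (eN @ eN) / s2_N + (eB @ eB) / s2_B + (eC @ eC) / s2_C \
                + 1.0 / FLAT_VAR
            lin = (eN @ rN) / s2_N + (eB @ rB) / s2_B + (eC @ rC) / s2_C
            beta_E = _gibbs.sample_normal_scalar(rng, prec, lin)

            # --- tooth-bone offset: pairs + tooth samples of both taxa
            rB = B - baseline[pB] - beta_E * eB
            rC = C - consumer[pC] - beta_E * eC
            prec = T.size / s2_T + (tB @ tB) / s2_B + (tC @ tC) / s2_C \
                + 1.0 / FLAT_VAR
            lin = T.sum() / s2_T + (tB @ rB) / s2_B + (tC @ rC) / s2_C
            mu_T = _gibbs.sample_normal_scalar(rng, prec, lin)

            # --- per-period means, with regression feedback through TP
            mu_reg = np.full(nJ, np.nan)
            mu_reg[id_idx] = Xid @ beta_reg
            corrB = beta_E * eB + mu_T * tB
            corrC = beta_E * eC + mu_T * tC
            sumB = np.bincount(pB, weights=B - corrB, minlength=nJ)
            sumC = np.bincount(pC, weights=C - corrC, minlength=nJ)
            fb_prec = np.where(identified, 1.0 / (mu_D ** 2 * s2_TP), 0.0)
            # baseline_j enters TP with coefficient -1/mu_D
            r_b = np.where(identified,
                           consumer / mu_D + lam - np.nan_to_num(mu_reg), 0.0)
            prec_b = n_deer / s2_B + fb_prec + 1.0 / FLAT_VAR
            lin_b = sumB / s2_B + r_b * fb_prec * mu_D
            baseline = lin_b / prec_b + rng.standard_normal(nJ) / np.sqrt(prec_b)
            r_c = np.where(identified,
                           np.nan_to_num(mu_reg) - lam + baseline / mu_D, 0.0)
            prec_c = n_bear / s2_C + fb_prec + 1.0 / FLAT_VAR
            lin_c = sumC / s2_C + r_c * fb_prec * mu_D
            consumer = lin_c / prec_c + rng.standard_normal(nJ) / np.sqrt(prec_c)

            # --- trophic discrimination factor: independence MH
            prec_q = D.size / s2_D + 1.0 / FLAT_VAR
            mean_q = (D.sum() / s2_D) / prec_q
            cand = mean_q + rng.standard_normal() / np.sqrt(prec_q)
            if cand > 0:
                diff = (consumer - baseline)[id_idx]
                tp_old = diff / mu_D + lam
                tp_new = diff / cand + lam
                m = Xid @ beta_reg
                logr = (((tp_old - m) ** 2).sum()
                        - ((tp_new - m) ** 2).sum()) / (2 * s2_TP)
                if np.log(rng.random()) < logr:
                    mu_D = cand
                    acc += 1
            prop += 1

            # --- period-level regression
            tp = (consumer - baseline)[id_idx] / mu_D + lam
            prec_r = Xid.T @ Xid / s2_TP + np.eye(preg) / FLAT_VAR
            lin_r = Xid.T @ tp / s2_TP
            beta_reg = _gibbs.sample_mvn_canonical(rng, prec_r, lin_r)
            err = tp - Xid @ beta_reg
            s2_TP, a_TP = _gibbs.sample_variance_halft(
                rng, float(err @ err), tp.size, a_TP)

            # --- variances
            s2_T, a_T = _gibbs.sample_variance_halft(
                rng, float(((T - mu_T) ** 2).sum()), T.size, a_T)
            errN = N - inter[tN] - beta_E * eN
            s2_N, a_N = _gibbs.sample_variance_halft(
                rng, float(errN @ errN), N.size, a_N)
            muBi = baseline[pB] + corrB
            muCi = consumer[pC] + corrC
            errB = B - muBi
            errC = C - muCi
            s2_B, a_B = _gibbs.sample_variance_halft(
                rng, float(errB @ errB), B.size, a_B)
            s2_C, a_C = _gibbs.sample_variance_halft(
                rng, float(errC @ errC), C.size, a_C)
            s2_D, a_D = _gibbs.sample_variance_halft(
                rng, float(((D - mu_D) ** 2).sum()), D.size, a_D)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                k = (it - mcmc.burn_in) // mcmc.thin
                if k < kept:
                    store["baseline"][c, k] = baseline + center
                    store["consumer"][c, k] = consumer + center
                    store["tp"][c, k, id_idx] = \
                        (consumer - baseline)[id_idx] / mu_D + lam
                    store["beta_reg"][c, k] = beta_reg
                    store["mu_T"][c, k] = mu_T
                    store["beta_E"][c, k] = beta_E
                    store["mu_Delta"][c, k] = mu_D
                    store["type_intercepts"][c, k] = inter
                    store["sigma_B2"][c, k] = s2_B
                    store["sigma_C2"][c, k] = s2_C
                    store["sigma_TP"][c, k] = np.sqrt(s2_TP)
                    store["mu_B"][c, k] = center + baseline[pB] \
                        + beta_E * eB + mu_T * tB
                    store["mu_C"][c, k] = center + consumer[pC] \
                        + beta_E * eC + mu_T * tC

    fit = PaleoFit(draws=store, periods=periods, identified=identified,
                   reg_columns=reg_columns, X=Xid, n_bear=n_bear,
                   n_deer=n_deer, spec=spec, mcmc=mcmc,
                   accept_rate_tdf=acc / prop if prop else float("nan"),
                   observed={"deer": B + center, "bear": C + center})
    return fit


def paleo_diagnostics(
    fit: PaleoFit, rng: np.random.Generator | None = None
) -> inference.FitDiagnostics:
    """Global fit diagnostics: PPP over deer + bear observations jointly,
    variance explained for the period-level regression, convergence, VIF."""
    rng = rng or np.random.default_rng(fit.mcmc.seed + 1)
    obs = np.concatenate([fit.observed["deer"], fit.observed["bear"]])
    mu = np.concatenate([fit.flat("mu_B"), fit.flat("mu_C")], axis=1)
    nB = fit.observed["deer"].size
    sB = np.sqrt(fit.flat("sigma_B2"))
    sC = np.sqrt(fit.flat("sigma_C2"))
    # per-observation sigma differs by taxon: fold into one RSS comparison
    resid = obs[None, :] - mu
    rss_obs = (resid ** 2).sum(axis=1)
    reps = np.concatenate([
        rng.standard_normal((mu.shape[0], nB)) * sB[:, None],
        rng.standard_normal((mu.shape[0], obs.size - nB)) * sC[:, None]],
        axis=1)
    ppp = float(np.mean((reps ** 2).sum(axis=1) >= rss_obs))
    fixed = fit.flat("beta_reg") @ fit.X.T
    r2m, r2c = inference.r2_mixed(fixed, np.zeros((fixed.shape[0], 0)),
                                  fit.flat("sigma_TP") ** 2)
    rhat, ess = fit.convergence()
    vifs = inference.vif(fit.X[:, 1:], fit.reg_columns[1:])
    return inference.FitDiagnostics(
        ppp=ppp, r2_marginal=float(np.median(r2m)),
        r2_conditional=float(np.median(r2c)), rhat=rhat, ess=ess, vif=vifs)
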
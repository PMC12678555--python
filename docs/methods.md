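# Methods

This note documents the models as implemented, the defaults and why they were
chosen, the sampler, what the synthetic generators do and do not emulate, and
the package's known limitations.

## Quantities and transforms

A diet record reports, per food category i, the relative frequency of
occurrence F_i = f_i / Σ f_i and/or the relative volume V_i = v_i / Σ v_i.
Volumes are converted to relative dietary energy contributions with
digestibility and energy-content correction factors,

    E_i = c_Di c_Ei V_i / Σ_i c_Di c_Ei V_i ,

and the trophic position of a record is the animal-prey energy share
P = Σ E_i over the vertebrate and invertebrate categories (carrion counts as
vertebrate prey).  E is invariant to any common rescaling of the c_D c_E
products and to relabeling categories within a trophic class; both
invariances are property-tested.

For regression, P values in the closed unit interval are compressed into the
open interval and probit-transformed,

    y = probit((P (n − 1) + 0.5) / n),

with n the number of trophic-position observations in the fitted dataset
(one per diet record; n = 210 at the default study size).  The transform is
strictly increasing and numerically invertible to 1e−12 over the whole
closed interval.  At n = 210 the compressed images of P = 0 and P = 1 are
0.5/210 ≈ 0.00238 and 0.99762 on the probability scale (±2.82 on the probit
scale); a reported post-transform range of 0.00034–0.99934 would instead
imply an effective n ≈ 1470, so the two conventions are not interchangeable.
n is therefore an explicit parameter (`MacroModelSpec.compress_n`), defaulting
to the number of trophic-position observations, and no silent choice is made.

The 20-category scheme ships with placeholder correction factors on the
scale of published digestibility/energy tables; real analyses should supply
the literature table via the categories CSV.  The math is insensitive to the
placeholder values in all tests because the generator and the fitting code
share whatever table is supplied.

## Macroecological model

Sub-model I (imputation).  For each dataset reporting both F and V, the
geometric-mean (standardized major axis) regression of log V on log F is
computed deterministically: slope = sign(cov) · sqrt(var(log V)/var(log F)),
intercept = mean(log V) − slope · mean(log F).  Natural logs are used; the
slope is base-invariant, the intercept is reported in natural-log units.
Items with F = 0 are retained as structural zeros in compositions but
excluded from the log-scale regression.  The pooled (intercept, slope) pairs
follow a bivariate normal with mean μ_β (flat normal prior) and covariance
Σ_β under a scaled-inverse-Wishart prior (s = 1, df = 2), which gives
half-t(2, 1) marginal standard deviations and a marginally uniform
correlation.  For datasets lacking V, a latent (intercept, slope) pair is
drawn from this distribution and latent log V_i ~ Normal(intercept + slope ·
log F_i, σ²_V).  The residual variance σ²_V is informed both by the latent
residuals and by the observed-V datasets' residuals about their own GM lines;
attaching the likelihood only to latent nodes would leave σ²_V essentially
prior-driven, so the complete datasets' residuals enter as data.

Sub-model II (process).  y_j ~ Normal(Σ_k β_k X_jk + γ_study + δ_species,
σ²_ε) with X = [intercept, log10 NPP, GSL, co-occurrence dummies
(reference = none)], flat Normal(0, 10⁴) priors on β and half-t(2, 1) priors
on all three SDs.  Predictors are standardized (after log10-transforming
NPP) by default, so effects are per-SD and match the partial-residual
display convention; raw-scale fits are available by switching
`standardize=False`.  The two-component variant replaces each environmental
predictor by its species mean (between/occurrence component) and
within-species deviation (population component); deviations sum to zero
within species and the two components reconstruct the predictor exactly.

Both sub-models share one posterior: the latent volumes determine P and
hence y for the imputed records, so the process regression feeds back into
the imputation.

## Paleoecological model

Collagen samples pass QC iff atomic C/N ∈ [2.9, 3.6] (endpoints inclusive)
and %C > 8 and %N > 3 (strict).  Ages (point values, ka BP) are binned into
eight half-open [lower, upper) stratigraphic bins — Meghalayan 0–4.2,
Northgrippian 4.2–8.2, Greenlandian 8.2–11.7, GS-1 11.7–12.8, GI-1
12.8–14.6, GS-2→GI-2 14.6–23.3, GS-3→GI-8 23.3–38.2, GS-9→GI-14 43.8–54.2 —
so a boundary age belongs uniquely to the older bin; the 38.2–43.8 ka
interval is deliberately unbinned and samples falling there are excluded
with a logged count.  The marine screen flags bear samples whose
(δ13C, δ15N) fall inside the convex hull of marine-mammal reference points
buffered by 1‰ (configurable); it is diagnostic only and never drops data.

The joint model couples:

* μ_T: mean of paired tooth−bone δ15N differences (n = 35 by default);
* β_E and material-type intercepts: linear model for reference δ15N of
  vegetation and herbivore tissues against elevation (n = 69);
* per-period means: each observation's expected δ15N is
  period mean + β_E · elevation + μ_T · 1{tooth}, so baseline_j and
  consumer_j are bone-equivalent, elevation-zero quantities — a bone sample
  at elevation 0 receives zero total correction;
* μ_Δ: mean of predator−prey discrimination pairs (n = 10);
* TP_j = (consumer_j − baseline_j)/μ_Δ + λ with λ = 2 (red deer is a strict
  herbivore), computed drawwise;
* the period-level regression TP_j ~ Normal(X_j β, σ²_TP) with
  X = [intercept, standardized log10 NPP, standardized GSL].  Per-period
  NPP/GSL are supplied as a table (sample means across that period's
  specimens by default; grid means are accepted through the same CSV).

Because μ_T, β_E and μ_Δ appear in several likelihood terms, every data
source informs them jointly and all their uncertainty propagates into TP and
into the regression.  The regression treats the TP_j as latent responses
inside the joint model, not as point estimates refit separately, so its
feedback sharpens the period means where the regression is informative.
Periods lacking either taxon have non-identified TP: they are flagged,
their TP draws are NaN, and they are excluded from the regression while
their (prior-dominated) period means are still sampled.

### Shift equivariance

Adding a constant to every bear and deer δ15N must leave all TP posteriors
unchanged.  With proper Normal(0, 10⁴) priors on the period means this holds
only approximately (shrinkage toward 0 breaks it at order prior-precision /
data-precision).  The sampler therefore centers the δ15N responses at their
grand mean internally and adds the center back when storing draws: the flat
prior is then anchored at the grand mean — immaterial at variance 10⁴ — and
equivariance is exact drawwise, which the tests assert at 1e−8.

## Sampler

All model layers are linear-Gaussian with (scaled-inverse-gamma) variance
priors, so the posterior factorizes into conjugate blocks and is sampled by
blocked Gibbs.  The half-t(2, 1) SD priors are realized by parameter
expansion (inverse-gamma mixture), which keeps every variance update
conjugate; the 2×2 covariance uses the analogous inverse-Wishart mixture
with half-t margins and a marginally uniform correlation.  Two blocks are
not conjugate:

* the latent log-volume vectors (the response transform V → P → y is
  nonlinear).  Each iteration applies two Metropolis–Hastings moves per
  dataset, vectorized across datasets: an independence proposal from the
  imputation conditional (accepted on the process-likelihood ratio alone)
  and a random-walk move (scale 0.2, `MacroModelSpec.rw_step`).  Typical
  acceptance rates are ~0.7 and ~0.4 at the default study size;
* μ_Δ, which enters the regression through 1/μ_Δ.  It is updated by an
  independence proposal from its conjugate conditional given the
  discrimination pairs, accepted on the regression-likelihood ratio;
  non-positive proposals are rejected, which keeps the TDF positive (with
  10 pairs around 3.3 ± 0.9‰ the truncation is never active in practice).

Energy shares are computed after subtracting the per-dataset maximum log
volume, so the (scale-invariant) normalization never overflows.

Chains are seeded independently via `numpy` seed sequences; a fixed
configuration and seed reproduce all draws bit for bit.  The production
preset mirrors the analyses' published settings (5 chains × 201,000
iterations, burn-in 1,000, thinning 100 → 10,000 draws);
`MCMCConfig.reduced()` (2 × 2,000, burn-in 500, no thinning) is the test and
smoke-run preset.  Tests and the acceptance script use reduced or
intermediate settings (up to 3 × 4,000) because the conditionals mix well:
split-R-hat on the reported parameters is typically within warning range,
and the sampler emits a warning listing any parameter with split-R-hat >
1.01.

## Summaries and diagnostics

Equal-tailed intervals use linear interpolation of order statistics; 50%
intervals are nested in 90% intervals by construction.  The probability of
direction is the fraction of draws sharing the median's sign, zeros counted
with the median's side, so p_d ∈ [0.5, 1].  The posterior predictive p-value
compares the observed RSS about each draw's fitted mean with the RSS of a
replicate drawn from that draw's likelihood; in the zero-noise degenerate
case ties count as replicate ≥ observed, giving 1.  For the macro model the
PPP uses the directly observed responses only (imputed records have no
observed y).  r²_marginal/r²_conditional follow the mixed-model variance
partition, computed per draw and summarized by medians.  VIF is computed
per fixed-effect column against the others; perfect collinearity reports
infinity with a warning rather than aborting.  Partial
(component + residual) values condition the remaining standardized
predictors at 0 and summarize the component line by 50/90% ETIs.

## Synthetic generators

The macro generator draws environmental covariates with a controllable
NPP–GSL correlation (0.61 by default, the structure the model is exercised
against; GSL is rounded to whole months, which attenuates the realized
correlation by a percent or two), assigns study/species structure
(210/155/7), simulates y from the probit-scale mixed model, inverts the
compression to get P, and builds compositions by splitting P among 2–4
animal categories and 1−P among plant categories with symmetric Dirichlet
weights; volumes invert the energy formula exactly and frequencies come
from volumes through per-dataset (intercept, slope) pairs drawn from the
bivariate pool (slopes resampled if below 0.2 to keep the line invertible),
with renormalization.  Default fixed effects are the effect sizes the model
family is meant to detect (−0.18 NPP, −0.41 GSL, −0.50 subordinate, +0.059
dominant per SD).  What it does not emulate: real sampling error in F and V
from finite scat counts, rounding and item-aggregation conventions of real
studies, spatial autocorrelation, and any phylogenetic structure among
species effects.  Passing recovery tests therefore show the estimator is
correct and calibrated when its assumptions hold, not that real diet tables
satisfy those assumptions.

The paleo generator simulates per-period deer and bear δ15N with elevation
and tooth biases applied, reference tables at the default sizes (35/69/10),
QC fields that pass by default with a configurable contamination rate, and
terrestrial δ13C far from the marine envelope.  Per-period trophic positions
come from the regression truth (−0.17, −0.19 per SD) plus noise
(σ_TP = 0.08).  The per-period NPP/GSL defaults form a stylized
glacial–Holocene contrast constrained to corr(log10 NPP, GSL) = −0.06
across the 8 periods, the weak-correlation design the regression assumes.
Not emulated: age uncertainty (ages are exact within bins), regional
structure in the baseline beyond elevation, and taphonomic biases.

## Problem sizes used in tests

Recovery tests run 20 replicates per model at the realistic sizes (macro
n = 200 with 50% volumes missing; paleo 219 + 372 over 8 periods) with
reduced chains (2 × 2,000), and assert 90%-interval coverage of at least
15/20 — the lower binomial band around the nominal 0.9.  Diagnostic
calibration uses a conjugate linear regression sampled directly (50 PPP
replicates, 20 null-slope p_d replicates), asserting PPP ∈ (0.2, 0.8) in at
least 80% and p_d > 0.95 in at most 4/20 (the event has probability 0.10
under the null; P(X ≥ 5 | Binomial(20, 0.1)) ≈ 0.04).

## Limitations

* The sampler is specific to these model families; it is not a general PPL
  backend, though all outputs are plain labeled draw arrays and every
  diagnostic operates on draw tables, not sampler internals.
* Single imputation structure: volumes are missing completely per dataset
  (all or none), matching the data layout; partially reported volumes within
  a dataset are rejected at read time.
* Dating uncertainty is out of scope: calibrated point ages are inputs, and
  samples in the 38.2–43.8 ka gap are excluded rather than smeared across
  bins.
* No model comparison (WAIC/LOO), spatial autocorrelation or phylogenetic
  regression; the variance structure is exactly the one described above.
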
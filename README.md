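# ursatroph

Bayesian hierarchical models of trophic position in bears, for
macroecologists and paleoecologists working on omnivore diet flexibility.

Bears span nearly the whole carnivory–omnivory–herbivory gradient, and their
trophic position is a flexible trait rather than a species constant.  This
package implements two linked analyses of that flexibility:

1. **Macroecological model.**  Diet compositions from scat and stomach
   studies across the ranges of the seven extant terrestrial bear species are
   converted to the *relative dietary energy contribution of animal prey*
   P ∈ [0, 1] using per-category digestibility (c_D) and energy-content (c_E)
   correction factors, E_i = c_Di c_Ei V_i / Σ c_Di c_Ei V_i.  Studies that
   report only the relative frequency of occurrence F (not the relative
   volume V) are handled by a hierarchical imputation layer: per-dataset
   geometric-mean (standardized major axis) regressions of log V on log F
   feed a bivariate-normal pool of intercepts and slopes, from which latent
   volumes are drawn so imputation uncertainty propagates into everything
   downstream.  The compressed probit of P,
   y = probit((P(n−1) + 0.5)/n), is regressed on log10 NPP, growing season
   length and co-occurrence with dominant/subordinate bear species, with
   random intercepts for study and species.  A two-component variant splits
   each environmental predictor into species-mean ("occurrence") and
   within-species ("population") components by group-mean centering.

2. **Paleoecological model.**  Collagen δ15N of European brown bears over the
   last 55 ka, with red deer as the herbivore baseline.  A single joint
   posterior couples the tooth–bone offset μ_T, the elevation effect β_E,
   per-period bias-corrected baseline and consumer means, the trophic
   discrimination factor μ_Δ, the per-period trophic position
   TP_j = (consumer_j − baseline_j)/μ_Δ + λ (λ = 2 for a strict-herbivore
   baseline), and a period-level regression of TP on log10 NPP and growing
   season length.

All location parameters carry flat Normal(0, 10⁴) priors; all variances carry
scaled-inverse-gamma (s = 1, df = 2) priors, i.e. half-t(2, 1) standard
deviations.  Posteriors are summarized by medians, 50%/90% equal-tailed
intervals and the probability of direction p_d; global fit is checked with an
RSS-based posterior predictive p-value and marginal/conditional r².
Sampling uses a blocked Gibbs sampler written for these model families, with
Metropolis-within-Gibbs steps for the two non-conjugate blocks (latent
log-volumes; μ_Δ).  A synthetic-data module generates both kinds of dataset
from the models' own generative processes with known ground truth, at the
default study sizes (210 diet records / 155 studies / 7 species; 219 bear and
372 deer samples over 8 time bins).

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
data (simulate → fit → calibrate).  For instance:

```sh
python analysis/03_simulate_paleo.py
python analysis/04_fit_paleo.py
```

prints the per-period trophic position of the brown bear and the period-level
regression (reduced chains, 3 × 4000):

```
       period  n_bear  n_deer  identified  median  eti90_lo  eti90_hi   pd
   Meghalayan      30      60        True    2.35      2.24      2.46 1.00
Northgrippian      30      60        True    2.35      2.24      2.47 1.00
 Greenlandian      25      50        True    2.32      2.20      2.45 1.00
         GS-1      20      40        True    2.71      2.57      2.88 1.00
         GI-1      25      40        True    2.67      2.54      2.83 1.00
    GS-2_GI-2      30      50        True    2.60      2.48      2.74 1.00
    GS-3_GI-8      40      50        True    2.94      2.79      3.12 1.00
   GS-9_GI-14      19      22        True    2.51      2.36      2.68 1.00

parameter  median  eti90_lo  eti90_hi     pd
      npp  -0.109    -0.243    +0.031  0.915
      gsl  -0.162    -0.299    -0.033  0.972
PPP = 0.51
```

Reading this: a trophic position of 2 is a strict herbivore; the synthetic
bears sit between 2.3 (productive Holocene bins) and 2.9 (the glacial
GS-3–GI-8 bin), and the regression slopes say trophic position falls by about
0.11 and 0.16 trophic-level units per standard deviation of log10 NPP and of
growing season length — both negative, as in the generating truth
(−0.17, −0.19).  PPP ≈ 0.5 indicates adequate global fit.

The same objects are available as a library:

```python
from ursatroph import (MCMCConfig, fit_paleo, gen_paleo, PaleoTruth)

samples, refs, env, truth = gen_paleo(PaleoTruth(seed=1))
fit = fit_paleo(samples, refs, env, MCMCConfig.reduced(seed=2))
print(fit.tp_table())
```

and from the shell via the `ursatroph` CLI (`simulate-macro`,
`simulate-paleo`, `fit-macro`, `fit-paleo`, `qc`).

## Layout

- `src/ursatroph/` — the package: `diet`, `macro`, `isotopes`, `paleo`,
  `inference`, `synthetic`, `workflow`, `cli`.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `docs/methods.md` — model details, priors, numerical choices, limitations.
- `tests/` — pytest suite (unit, property and acceptance tests).
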
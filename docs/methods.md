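# Methods

## The mixing model and its assumptions

The package implements the marginalised residual-error formulation of a
two-isotope stable-isotope mixing model. Each consumer is assumed to
assemble its tissue from per-individual latent draws of the K source
distributions, shifted by a diet-to-tissue trophic discrimination
factor (TDF), plus an individual residual. Integrating the latent
source values out gives, per isotope j,

    mean_j(p)     = Σ_k p_k (μ_jk + Δ_j)
    variance_j(p) = Σ_k p_k² (σ_jk² + τ_j²) + σ_res,j²

Assumptions worth stating plainly:

- **Isotopes are conditionally independent.** No source covariance is
  modelled; it is not estimable from per-isotope summary tables, and
  the synthetic generator draws isotopes independently to match.
- **Sources enter through summary moments** (mean, SD, n per isotope),
  not raw samples. Pooled sources (mushrooms + phloem for fall,
  mushrooms + pollen for summer) use the exact concatenation identity,
  so pooling from moments equals pooling from raw data.
- **No concentration dependence, no hierarchical structure** across
  individuals, at most 2 isotopes. Groups are fitted independently.
- The residual SD absorbs individual-level variation (tissue turnover,
  within-group diet heterogeneity) the mixture terms do not capture.

Because the likelihood is normal with a common mean/variance across
consumers, the data enter only through n, Σx, Σx² per isotope. The
sampler exploits this (the per-iteration cost is independent of n),
and it also motivates a reconstruction feature: when only a group's
published mean/SD are available, `gen_consumers_from_moments(...,
exact_moments=True)` rescales the simulated sample so its moments equal
the published values exactly. This removes resampling noise that the
original data did not have — important for small groups (n = 7), where
a free normal draw shifts the group mean by ~SD/√7 ≈ 0.5 ‰ and can move
a posterior diet proportion by more than 0.1.

## Priors, parameterisation, and sampling

- Dirichlet(1, …, 1) on p (uninformative); Uniform(0, 20 ‰) on each
  residual SD. The TDF defaults to (3.4, 2.4) ‰ with SD 0; a nonzero
  TDF SD adds on the variance scale.
- Unconstrained coordinates: additive log-ratio transform of p with the
  **last source as reference**, and a scaled-logit transform of each
  residual SD. Both Jacobians are included, so the stated priors are
  exact on the constrained scale.
- Adaptive random-walk Metropolis: a single Gaussian proposal over all
  K+1 coordinates, scale initialised at 2.38/√dim and adapted in
  batches of 50 iterations **during burn-in only** (diminishing
  Robbins–Monro steps, targeting acceptance in 0.2–0.5), which
  preserves the correct stationary distribution after burn-in.
- Defaults: 3 chains, 10,000 burn-in, 40,000 iterations, thin 10, i.e.
  4,000 retained draws per chain. One user seed spawns independent
  per-chain streams via `numpy.random.SeedSequence`.
- Initialisation at the geometric (mixing-polygon) point estimate —
  the exact solve of Σ p_k μ'_jk = x̄_j with Σ p_k = 1, feasible only
  when the mean consumer lies inside the adjusted source polygon —
  floored at 0.01 and renormalised; uniform composition as fallback.
  A non-finite posterior at initialisation is retried with jitter up
  to 10 times before erroring.
- Diagnostics: split-chain R̂ per parameter (threshold 1.1; summaries
  are still produced above it, with a prominent warning), multi-chain
  effective sample size (FFT autocovariances, Geyer initial positive
  pair truncation), and per-chain acceptance rates.

## Availability regression

Annual seed and mushroom production is z-scored against the long-term
baseline (default 1994–2014) using the baseline mean and sample SD, not
the study-year subset. Individual δ¹³C is regressed on the two z-scores
plus 0/1-coded factors (season fall=0, group before-removal=0, area
control=0, sex F=0) and a group×area interaction. Reference levels were
chosen so that "enriched in summer" appears as a positive summer
coefficient. Backward elimination drops the highest-p non-protected
term above α = 0.05, the interaction always eligible before its parent
main effects and never the reverse, ties broken toward the later
declared term; the seed and mushroom z-scores are never dropped
(variables of primary interest). The final model is the minimum-AIC fit
along the visited path. The AIC convention counts the residual variance
as a parameter: K = (#coefficients incl. intercept) + 1 and
AIC = −2·logL(σ̂²_MLE) + 2K, so a 4-slope model has K = 6. Candidate
tables report ΔAIC and standard Akaike weights.

## Removal-efficacy statistics

Camera counts follow the hourly rule for unmarked animals without
exclusive territories: all single-animal photographs within one
(transect, hour) count as one individual; a two-animal frame counts
two. Per-transect means include zero-count transects; the number of
transects always comes from the data. Mann–Whitney comparisons use the
first-sample U with half-credit ties (W can be fractional, and
W + W′ = n₁n₂ exactly). P-values are exact by full enumeration of
labelings when the data are tie-free and n₁+n₂ ≤ 20, otherwise a
tie-corrected normal approximation with continuity correction; an
explicit request for the exact method with tied data falls back with a
warning, since no exact null distribution exists under ties without a
permutation convention.

## Synthetic scenario: what it emulates, and what it does not

The default scenario encodes the study conditions: six diet items with
the published isotope moments; seven consumer groups with the published
group sizes and diet compositions as generating truths; TDF (3.4,
2.4) ‰; a 21-year production series; and transect counts with a
treatment-area suppression effect.

Chosen-once calibrations where no published value exists:

- **Consumer residual SD 0.5 ‰ per isotope.** The within-group spread
  of consumer values (≈0.4–0.85 ‰ in δ¹³C) bounds the plausible range
  once mixture variance is accounted for; 0.5 ‰ sits in the middle.
- **Regression noise σ = 0.6 ‰, n = 110.** Back-solved from the
  selected model's printed AIC (211.35 at K = 6, n = 110 ⇒ σ̂ ≈ 0.60);
  the generating coefficients are the published final-model estimates.
- **Log-normal production.** The printed study-period seed moments
  (mean 181.2/m², SD 212.1) imply CV > 1, which rules out a normal
  model on non-negative support; meanlog/sdlog are the exact moment
  inversion of the printed mean/SD for each resource. Year-to-year
  correlation between seeds and mushrooms defaults to 0 (unknown), with
  a correlation parameter exposed.
- **Negative-binomial counts** (control mean 12, dispersion 3.5,
  treatment multiplier 0.35, 6 transects/area): printed per-transect
  SDs exceed means, ruling out Poisson; the area multiplier matches the
  printed treatment/control camera means (4.17 vs 12.17).

What the generator does **not** emulate: temporal autocorrelation in
production, spatial structure among transects, isotope covariance
within sources or consumers, repeated measures of the same individual,
and season-specific source availability. Passing recovery tests
therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to these real-data features.

## Numerical choices and degenerate inputs

- Group summaries use the sample (n−1) SD and keep full precision;
  rounding to 2 decimals happens only in report tables.
- Welch t-test with both groups at zero variance and equal means
  returns (t = 0, p = 1) by convention and logs the degeneracy.
- One-way ANOVA with all observations identical returns F = 0, p = 1;
  zero within-group variance with unequal means reports p ≈ 0 with a
  warning.
- The geometric point estimate raises on collinear sources (singular
  mixing polygon) and on K > 3 (under-determined with two isotopes).
- Out-of-support posterior draws get log-density −∞, never an
  exception; every retained draw satisfies |Σp − 1| < 1e-12 because p
  is produced by a softmax.
- Implausible delta values (δ¹³C outside [−40, 0], δ¹⁵N outside
  [−10, 20]) warn rather than error; instrument precision (±0.10 ‰ C,
  ±0.2 ‰ N) is metadata only and is not propagated into any likelihood.

## Problem sizes used in the test suite

Recovery and oracle tests run the sampler at reduced settings (e.g.
3 chains × 1,500 + 6,000 iterations, thin 3) chosen so Monte-Carlo
error stays well inside each test's tolerance; the headline
reproduction, convergence, and quadrature-oracle checks use the full
default settings. The quadrature oracle marginalises a 2-source problem
on a 1,001-point simplex grid × 200-point residual-SD grids, using the
factorisation of the likelihood across isotopes.

## Known limitations

- Random-walk Metropolis mixes slowly for K ≳ 5 sources or strongly
  collinear source geometries; the study system needs K = 3.
- Equal-tailed credible intervals can include 0 or 1 exactly for
  near-boundary proportions; no highest-density option is provided.
- The backward-elimination path explores at most one model per dropped
  term; the AIC minimum is over the visited path, not all subsets (the
  path-visited optimum is what the procedure defines).
- Exact Mann–Whitney p-values are refused (with fallback) under ties;
  a permutation test would handle ties exactly but is not implemented.
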
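# nichemix

Stable-isotope dietary-niche analysis for consumers whose diets mix a
small number of isotopically distinct food sources — built around the
squirrel system in which a native larder-hoarding red squirrel and an
introduced Abert's squirrel partition conifer seeds, hypogeous fungi
(truffles), and a grouped mushrooms/phloem source.

The package provides four analysis stages plus a synthetic-data
generator, usable as a library or through the `nichemix` command line:

1. **Isotope core** — delta-notation arithmetic, group summaries
   (mean/SD/n per isotope), Welch-test screening of source
   distinctness, and exact moment-based pooling of indistinct sources.
2. **Mixing model** — a two-isotope, K-source Bayesian stable-isotope
   mixing model (SIMM) with residual error, fitted by an adaptive
   random-walk Metropolis sampler written in this package.
3. **Availability model** — annual food production z-scored against a
   long-term baseline, and OLS regression of individual δ¹³C on
   availability with backward elimination and AIC selection.
4. **Field stats** — removal-efficacy statistics: the hourly camera
   photograph counting rule, per-transect means, and Mann–Whitney U
   tests (exact by enumeration when tie-free and small, tie-corrected
   normal otherwise).

## The model

A consumer's tissue isotope value `X_ij` (individual *i*, isotope *j* ∈
{δ¹³C, δ¹⁵N}) is a proportion-weighted mixture of TDF-shifted sources:

    X_ij ~ Normal( Σ_k p_k (μ_jk + Δ_j),
                   Σ_k p_k² (σ_jk² + τ_j²) + σ_res,j² )

with diet proportions **p** on the simplex, source moments (μ_jk,
σ_jk), trophic discrimination factor Δ = (3.4, 2.4) ‰ (diet → hair, SD
τ configurable), and per-isotope residual SDs. Priors are
Dirichlet(1,…,1) on **p** and Uniform(0, 20 ‰) on each σ_res. Sampling
uses an additive log-ratio transform of **p** (Jacobian-corrected, so
the prior stays exactly Dirichlet), runs 3 chains of 10,000 burn-in +
40,000 iterations thinned by 10 by default, and reports posterior means
with equal-tailed 95% credible intervals, split-R̂, effective sample
sizes, and acceptance rates.

## Worked example

```sh
nichemix simulate --out demo --seed 42
nichemix mix --consumers demo/consumers.csv --sources demo/sources.csv \
    --out demo --seed 42 --chains 3 --burnin 2000 --iters 10000 --thin 5
nichemix report --estimates demo/diet_estimates.csv --out demo/report.txt
```

The simulate stage writes sources, consumers, production, and transect
CSVs for the default scenario (seven consumer groups with the study's
group sizes and diet compositions). The mix stage then recovers each
group's diet; for the native red squirrel group the report reads

```
MG_red  fall  n=85  red_seeds=0.67 [0.60, 0.75]  truffles=0.24 [0.20, 0.27]  epphlo=0.09 [0.02, 0.15]
```

i.e. a fall diet of ~67% conifer seeds, ~24% truffles, and ~9% grouped
mushrooms/phloem, with 95% credible intervals — matching the generating
proportions (0.66/0.25/0.09) within Monte-Carlo error. The availability
stage on the same scenario selects the model `c + m + s + g` (seeds,
mushrooms, season, group; K = 6) and prints a positive seed coefficient
and a negative mushroom coefficient: years rich in δ¹³C-depleted fungi
pull consumer δ¹³C down, seed-rich years push it up.

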
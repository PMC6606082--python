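# Methods

## The estimation problem

National household surveys such as the DHS are powered for national and
regional estimates, yet programme targeting often needs district-level
numbers. `districtprev` implements small-area estimation of the prevalence
of adolescent first births — the share of women aged 20–29 at survey whose
first live birth occurred before age 16, at 16–17, at 18–19, or before 20
(completed years) — by borrowing strength across neighbouring districts
with a Bayesian spatial logistic regression.

## Model

For woman *i* in district *j*:

```
y_ij ~ Bernoulli(p_ij)
logit(p_ij) = x_ij' β + f_struc(j) + f_unstruc(j)
```

The covariate vector holds dummy-coded urban/rural residence, education
(none / primary / secondary / higher) and wealth quintile (1–5), with
rural, no-education and lowest-quintile reference levels. `f_struc` is an
intrinsic CAR (Besag) field over the district contiguity graph: improper
Gaussian with precision `τ_struc (D − W)`, identified by a sum-to-zero
constraint per connected component. `f_unstruc` is i.i.d.
`Normal(0, 1/τ_unstruc)`. The `besag` variant drops `f_unstruc`; `none`
drops both. Each of the four outcome brackets is fitted as an independent
binary model (a woman whose first birth falls outside the bracket counts
as 0; an exclusion flag for earlier births is available but off by
default, since the bracket shares are additive fractions of all women).

Priors are the diffuse conventions of areal disease mapping:
`β ~ Normal(0, 31.6²)` (precision 0.001) and
`τ_struc, τ_unstruc ~ Gamma(shape 1, rate 0.0005)`. Both are overridable
through `ModelSpec`; precisions can also be pinned (`tau_fixed`), which is
what the brute-force oracle tests use. No BYM2-style rescaling of the ICAR
precision is applied (a deliberate match to the older model family this
pipeline reimplements); the unscaled and scaled variants differ only in
the interpretation of `τ_struc`.

## Inference

Exact MCMC via Pólya-Gamma data augmentation. Conditional on
`ω_i ~ PG(1, ψ_i)` the logistic likelihood is Gaussian in the linear
predictor, so one Gibbs sweep is:

1. `ω_i ~ PG(1, ψ_i)` — drawn with Devroye's exact alternating-series
   rejection sampler (numba-compiled; fractional shapes, needed by
   tempered chains, use the truncated sum-of-gammas representation).
2. `(β, f_struc, f_unstruc)` jointly from one multivariate Gaussian whose
   precision is `A'ΩA + blockdiag(τ_β I, τ_struc Q, τ_unstruc I)`. The
   ICAR sum-to-zero constraint is imposed *exactly* by conditioning the
   draw on the component-sum functionals (conditioning by kriging): the
   unconstrained draw `θ` is corrected to
   `θ − ΣC'(CΣC')⁻¹Cθ` with one constraint row per connected component.
   Isolated districts form singleton components, so their structured
   effect is pinned at zero and only the unstructured term remains.
3. Conjugate Gamma updates: `τ_struc | u` with shape increment
   `rank(Q)/2 = (J − #components)/2`, and `τ_unstruc | v` with `J/2`.

A tiny jitter (1e-10) on the structured block keeps the Cholesky stable
when a component carries no data; the constraint removes the affected
directions, so it does not bias the draw. Split-R̂ is computed on every
fixed effect after the run and a `ConvergenceWarning` (with the values
attached) is raised above 1.1 — never silently.

The structured/unstructured *split* mixes slowly: only `u + v` is strongly
likelihood-identified, so `τ_struc` and `τ_unstruc` can trade places over
long stretches of chain. District prevalence depends only on the sum, so
predictions are robust to this; users reading the individual precisions
should run long chains and check the traces.

## District prediction and mapping

Per draw *s*, the predicted prevalence of district *j* is the average of
`logistic(x_i'β_s + f_spat,s(j))` over the women sampled in *j* (the
observed within-district covariate composition — the default; national
composition and reference-level profiles are options). Districts with no
sampled women use the study-wide composition with their own spatial
effect and are flagged `extrapolated`. Summaries are the empirical mean,
SD and equal-tailed 95% interval of the per-draw prevalences; the interval
width is the mapped uncertainty measure. Choropleth GeoJSON output uses
five quantile classes by default, with explicit under/overflow classes for
fixed breaks rather than silent clamping.

## Model comparison

DIC uses Spiegelhalter's construction: `Dbar + p_D` with
`p_D = Dbar − D(θ̄)` and `θ̄` the posterior mean of `(β, f_spat)`. Because
the deviance is convex in the linear predictor and the predictor is linear
in `θ`, Jensen's inequality makes this `p_D` non-negative here; the
negative-`p_D` warning path exists defensively for externally constructed
draw sets.

The marginal log-likelihood is estimated by thermodynamic integration
over the power posterior `∝ L^t × prior`, trapezoid rule on the ladder
`t_i = (i/20)^5` (21 rungs, concentrated near `t = 0` where the integrand
moves fastest under diffuse priors). The tempered chains reuse the PG
Gibbs kernel with shape-`t` latent variables (`t = 0` samples the prior
exactly). Standard errors combine per-rung batch-means errors through the
trapezoid weights. Absolute MLL values are estimator-dependent; only
differences between models on the same data are meaningful, and they are
not comparable to values produced by Laplace-type approximations.

## The synthetic survey generator

The generator emulates a two-stage cluster survey of the kind the pipeline
targets: a planar lattice of equal-area square districts (default 5×15 =
75), 289 clusters placed uniformly (district chosen ∝ area, point uniform
inside), ~15.3 women per cluster (Poisson, min 1, giving ≈ 4,400 women),
urban flags per cluster, covariates drawn independently per woman, and
Bernoulli outcomes from the exact model above.

Age at first birth is one categorical draw per woman over the brackets,
with cumulative probabilities `logistic(α_a + η)` at cut ages 16/18/20 —
so bracket shares are additive by construction and the <20 outcome is
exactly logistic. The cut-points `α` are calibrated by root-finding so the
population-marginal cumulative prevalences (covariate mix enumerated
exactly, spatial effect integrated by Gauss–Hermite quadrature) hit 4.8%,
21.2%, 43.3% — the national totals reported for the 2011 Nepal DHS, whose
structure the generator mirrors. Coefficient defaults are the log-odds
contrasts implied by that survey's published stratified percentages
(e.g. urban −0.52, higher education −3.50, top quintile −1.38); since
covariates are drawn independently, these marginal contrasts slightly
overstate joint gradients, which is acceptable for a generator whose job
is realistic signal strength, not causal fidelity. Default precisions
`τ_struc = 3, τ_unstruc = 12.5` give a combined district-effect SD ≈ 0.45
on the log-odds scale, matching the reported district prevalence spread
(roughly 26–67% for the <20 bracket).

Cluster displacement mimics the DHS anonymisation procedure: uniform
angle, radius uniform on `[0, cap]` with caps 2 km (urban) / 5 km (rural);
the optional "1% of rural clusters up to 10 km" rule is off by default.
Displaced clusters are re-linked to districts by buffering the displaced
point with its cap and assigning the district of greatest overlap (exact
ties break to the smallest district id — deterministic and auditable).
Weights default to 1.0; an optional two-stage scheme (lognormal cluster
factor × urban/rural stratum factor) exercises the weighted tabulation.
Whether real DHS weights vary appreciably across clusters in the target
setting is unknown to us; the scheme is a documented guess.

What the generator does *not* emulate: real geography (equal-area convex
districts only), population-density gradients, covariate correlation
(wealth–education–residence are independent here), marriage as a mediator,
survey non-response, or recall error in reported ages. Tests passing on
synthetic data therefore validate the *machinery* — not the
substantive conclusions one would draw from any particular real survey.

## Validation experiment designs

All in `districtprev.validation`, run by both the test suite and
`scripts/acceptance.py`; sizes were chosen as the smallest that make the
checks sharp:

- **Posterior oracles.** Intercept-only model (30/100 successes, prior SD
  10) against 1-D quadrature; and a 3-district path-graph BYM toy (12
  observations, fixed `τ`) against a brute-force 81³ grid posterior — the
  grid is feasible because, with fixed precisions, the prior of
  `η_j = β₀ + u_j + v_j` is the 3-D Gaussian
  `σ_β²11' + Q⁺/τ_s + I/τ_v` and the likelihood depends on `η` alone.
- **Recovery & calibration.** 50 replicates of ≈5,000 women in 60
  districts at the default effect sizes, displacement off so that
  cluster–district assignment is exact and the experiment isolates
  inference (assignment is validated separately). First 20 replicates:
  each true coefficient covered by its 95% interval. All 50: pooled
  district-interval coverage against the realised true district
  prevalences, and the rank correlation of interval width with district
  sample size. Chains 4,000 iterations (1,200 burn-in, thin 2).
- **Model-selection direction.** 20 replicates, 100 districts × ≈50 women,
  purely unstructured heterogeneity (effect SD 1): DIC(BYM) < DIC(Besag).
  Many districts are needed because the per-district DIC advantage of the
  correctly specified model is a fraction of a point — the ICAR field can
  imitate iid noise by roughening, so the aggregate margin (typically 1–3
  DIC points, same order as published comparisons of this model pair)
  only separates from Monte-Carlo noise when accumulated over ~100
  districts.
- **Evidence toys.** Single Bernoulli with uniform prior (evidence ½) and
  Beta-binomial (n=20, y=7, Beta(2,2)) against closed forms, via the
  generic adaptive-RW power-posterior route; the PG-Gibbs route is checked
  against 1-D quadrature evidence separately in the unit tests.
- **Geoprocessing.** 20 random disc/border configurations on a 3×3
  lattice: geometric overlap areas vs a 400×400 grid-sampling oracle
  (within 1% of disc area) and identical greatest-overlap winners.
- **Determinism.** Identical config+seed twice: byte-identical CSVs,
  identical draw arrays, identical GeoJSON properties.

## Known limitations

- With weakly identified district effects the flat-on-precision Gamma
  prior shrinks aggressively; district interval coverage in the recovery
  study sits a little below nominal (≈92–94% pooled), and is sensitive to
  the hyperprior (e.g. `Gamma(0.5, 0.005)` moves it toward 95%). The
  conventional default is kept because this pipeline reimplements that
  model family's standard behaviour.
- End-to-end coverage with displacement on is a few points lower again:
  ~4% of clusters are linked to a neighbouring district even with the
  greatest-overlap rule, a data limitation no assignment scheme removes.
- The `τ_struc`/`τ_unstruc` split is only weakly identified (see above).
- Thermodynamic-integration MLL values are estimator-specific; orderings,
  not levels, are comparable across software.
- Design-based variance for the weighted cross-tabs is out of scope; the
  tables are point estimates.
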
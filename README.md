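# districtprev

District-level small-area estimation of adolescent first-birth prevalence
from DHS-style household surveys, using Bayesian spatial logistic
regression (Besag / BYM) with exact MCMC.

## Who this is for

National surveys like the DHS report adolescent-motherhood indicators at
national or regional level; programme targeting needs them per district,
where direct survey estimates are too noisy or absent. This package is for
epidemiologists and demographers who want to (a) reproduce the standard
survey-weighted cross-tabulations of first births by age bracket (<16,
16–17, 18–19, <20 completed years) and socioeconomic strata, and (b)
smooth district prevalence spatially with full uncertainty quantification
— plus a seeded synthetic-survey generator so every stage can be tested
without restricted microdata.

## The model

For woman *i* in district *j*, with `y` indicating a first birth in the
bracket of interest:

    y_ij ~ Bernoulli(p_ij)
    logit(p_ij) = β₀ + β₁x_ij + … + β_k x_ij + f_spat(j)
    f_spat(j)   = f_struc(j) + f_unstruc(j)

where `f_struc` is an intrinsic CAR (Besag) field on the district
contiguity graph (sum-to-zero per connected component) and `f_unstruc` is
an i.i.d. Gaussian district effect; together they form the
Besag–York–Mollié (BYM) model. Covariates are urban/rural residence,
education and wealth quintile (dummy-coded against rural / no education /
lowest quintile). Inference is exact MCMC via Pólya-Gamma data
augmentation (conditionally Gaussian updates for all coefficients and
effects, conjugate Gamma updates for the precisions). Models are compared
by DIC and by thermodynamic-integration marginal log-likelihood; district
predictions are posterior summaries of composition-averaged prevalence,
with the 95% credible-interval width as the mapped uncertainty measure.
See `docs/methods.md` for details and design choices.

Displaced cluster coordinates (the DHS anonymisation shifts clusters up to
2 km urban / 5 km rural) are handled the standard way: each cluster is
buffered by its displacement cap and linked to the district with the
greatest overlap.

## Worked example

```python
import districtprev as dp

# 1. simulate a DHS-like survey: 75 districts, 289 clusters, ~4,400 women
cfg = dp.ScenarioConfig(seed=1)
dmap = dp.generate_district_lattice(cfg.n_districts_rows, cfg.n_districts_cols, cfg.cell_size_km)
adj = dp.build_adjacency(dmap, "queen")
survey = dp.generate_survey(cfg, dmap, adj)

# 2. weighted cross-tabulation by wealth quintile (percent)
table = dp.weighted_prevalence(survey, "wealth_quintile")
print(table.as_percent())
print("lowest:highest ratio (<20):", dp.group_ratio(table, 1, 5, "lt20"))

# 3. link displaced clusters to districts, fit the BYM model for <20
assignment = dp.assign_clusters(survey.clusters, dmap)
spec = dp.ModelSpec(bracket="lt20", spatial="bym",
                    sampler=dp.SamplerSettings(n_iter=4000, n_burnin=1000, n_thin=1, seed=2))
design = dp.build_design(survey, spec, assignment)
fit = dp.fit_model(spec, design, adj)
s = dp.posterior_summary(fit, "beta:urban")
print(f"urban log-odds: {s.mean:.2f} [{s.q025:.2f}, {s.q975:.2f}]")

# 4. compare against Besag-only by DIC; summarise district estimates
fit_b = dp.fit_model(dp.ModelSpec(bracket="lt20", spatial="besag", sampler=spec.sampler), design, adj)
print(dp.compare_models([dp.compute_dic(fit, design, "bym"),
                         dp.compute_dic(fit_b, design, "besag")]))
estimates = dp.predict_district_prevalence(fit, design)
print(dp.summarize_sd_distribution(estimates))
worst = max(estimates, key=lambda e: e.ci_width)
print(f"widest interval: {worst.district_id} ({worst.n_women} women), "
      f"mean {worst.mean:.2f}, 95% CrI width {worst.ci_width:.2f}")
```

Output (about one minute on one CPU):

```
   lt16  16to17  18to19  lt20
1   7.0    22.6    24.9  54.5
2   4.0    21.8    24.5  50.3
3   5.6    16.6    24.5  46.6
4   2.8    11.8    18.8  33.3
5   2.2     9.4    16.5  28.1
lowest:highest ratio (<20): 1.9
urban log-odds: -0.49 [-0.65, -0.33]
model    dic  p_d  best_by_dic
  bym 5197.5 45.7         True
besag 5201.5 41.9        False
{'min': 0.0317, 'q1': 0.0391, 'median': 0.0429, 'mean': 0.0437, 'q3': 0.0467, 'max': 0.0608}
widest interval: d042 (16 women), mean 0.48, 95% CrI width 0.24
```

Reading it: the synthetic survey reproduces the expected socioeconomic
gradient (54.5% of lowest-quintile women had a first birth before 20
versus 28.1% in the highest quintile, a 1.9× ratio); the BYM fit recovers
the generating urban contrast (−0.52) inside its credible interval; DIC
prefers BYM over Besag-only; and the per-district posterior SDs of
prevalence run from about 0.03 to 0.06, widest where the district sample
is smallest.

The same stages are scriptable via the CLI
(`districtprev simulate|geoprep|tabulate|fit|run`), and
`districtprev run --config pipeline.yaml --out out/` executes the whole
pipeline (simulate → assign → tabulate → fit all brackets × structures →
compare → map) with a manifest of seeds and content hashes.

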
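"""End-to-end validation studies for the estimation pipeline.

These are the package's own verification experiments: closed-form and
brute-force oracles for the samplers and estimators, replicate simulation
studies for parameter recovery, interval calibration and model-selection
direction, and a grid-sampling oracle for the geoprocessing.  They are run
by the test suite and by ``scripts/acceptance.py``.

The published 2011 Nepal DHS cross-tabulation percentages used by the
ratio-arithmetic check are inputs here: the package recomputes the reported
wealth and residence ratios from those printed cells.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.special import betaln, expit, gammaln
from scipy.stats import spearmanr

from . import bym, geo, mapping, selection, synthetic
from .tabulate import ratio_from_percentages

# Published weighted cross-tabulation cells (percent of women 20-29 with a
# first birth in each bracket), 2011 Nepal DHS: wealth quintile rows and
# urban/rural residence rows.
NEPAL_2011_WEALTH_PCT = {
    "lowest": {"lt16": 5.8, "16to17": 24.5, "18to19": 28.6, "lt20": 58.4},
    "highest": {"lt16": 2.9, "16to17": 9.2, "18to19": 14.0, "lt20": 26.1},
}
NEPAL_2011_RESIDENCE_PCT = {
    "urban": {"lt16": 4.4, "16to17": 13.6, "18to19": 16.6, "lt20": 34.6},
    "rural": {"lt16": 4.9, "16to17": 17.7, "18to19": 24.5, "lt20": 47.1},
}
NEPAL_2011_TOTAL_PCT = {"lt16": 4.8, "16to17": 16.4, "18to19": 22.1, "lt20": 43.3}


def published_ratio_checks() -> dict[str, float]:
    """Recompute the reported wealth and residence prevalence ratios from
    the printed percentage cells (rounded half-up to one decimal)."""
    w, r = NEPAL_2011_WEALTH_PCT, NEPAL_2011_RESIDENCE_PCT
    return {
        "wealth_ratio_lt20": ratio_from_percentages(w["lowest"]["lt20"], w["highest"]["lt20"]),
        "wealth_ratio_16to17": ratio_from_percentages(w["lowest"]["16to17"], w["highest"]["16to17"]),
        "wealth_ratio_lt16": ratio_from_percentages(w["lowest"]["lt16"], w["highest"]["lt16"]),
        "residence_ratio_lt20": ratio_from_percentages(r["rural"]["lt20"], r["urban"]["lt20"]),
    }


def bracket_additivity_error(seed: int = 0) -> float:
    """Largest |lt16 + 16to17 + 18to19 - lt20| over all strata of all
    tabulations of a default synthetic survey (heterogeneous weights on)."""
    from .tabulate import SUB_BRACKETS, weighted_prevalence

    cfg = replace(synthetic.ScenarioConfig(seed=seed), heterogeneous_weights=True)
    dmap = synthetic.generate_district_lattice(cfg.n_districts_rows, cfg.n_districts_cols, cfg.cell_size_km)
    ds = synthetic.generate_survey(cfg, dmap)
    worst = 0.0
    for strat in ("total", "residence", "education", "wealth_quintile"):
        t = weighted_prevalence(ds, strat)
        for level in t.proportions.index:
            gap = abs(sum(t.proportion(level, b) for b in SUB_BRACKETS) - t.proportion(level, "lt20"))
            worst = max(worst, gap)
    return worst


# ---------------------------------------------------------------------------
# posterior oracles


def quadrature_oracle_error(seed: int = 31) -> float:
    """|MCMC - quadrature| for E[logistic(beta0)] in an intercept-only model
    with 30 successes of 100 and a Normal(0, 10^2) prior."""
    y = np.zeros(100)
    y[:30] = 1.0
    design = bym.DesignMatrix(y=y, X=np.ones((100, 1)), columns=["intercept"],
                              district_ids=np.array(["d1"] * 100, dtype=object))
    adj = geo.AdjacencyGraph(nodes=["d1"], edges=set())
    spec = bym.ModelSpec(spatial="none", prior_beta_sd=10.0,
                         sampler=bym.SamplerSettings(n_iter=6000, n_burnin=1000, n_thin=1, seed=seed))
    fit = bym.fit_model(spec, design, adj)
    mcmc = float(expit(fit.beta[:, 0]).mean())
    b = np.linspace(-8, 8, 20_001)
    logpost = 30 * b - 100 * np.logaddexp(0, b) - 0.5 * (b / 10.0) ** 2
    w = np.exp(logpost - logpost.max())
    oracle = float(np.trapezoid(expit(b) * w, b) / np.trapezoid(w, b))
    return abs(mcmc - oracle)


def grid_oracle_error(seed: int = 8) -> float:
    """Max |MCMC - grid| over the three district probabilities of the
    path-graph BYM toy with fixed precisions (12 observations)."""
    nodes = ["d1", "d2", "d3"]
    adj = geo.AdjacencyGraph(nodes=nodes, edges={("d1", "d2"), ("d2", "d3")})
    counts = {"d1": (3, 4), "d2": (1, 4), "d3": (2, 4)}
    y, dist = [], []
    for d, (s, n) in counts.items():
        y += [1.0] * s + [0.0] * (n - s)
        dist += [d] * n
    design = bym.DesignMatrix(y=np.array(y), X=np.ones((12, 1)), columns=["intercept"],
                              district_ids=np.array(dist, dtype=object))
    tau_s = tau_v = sd_b = 1.0
    spec = bym.ModelSpec(spatial="bym", prior_beta_sd=sd_b, tau_fixed=(tau_s, tau_v),
                         sampler=bym.SamplerSettings(n_iter=22_000, n_burnin=2000, n_thin=2, seed=seed))
    fit = bym.fit_model(spec, design, adj)
    mcmc_p = expit(fit.beta[:, [0]] + fit.f_spat()).mean(axis=0)

    q = adj.laplacian()
    sigma = sd_b**2 * np.ones((3, 3)) + np.linalg.pinv(q, hermitian=True, rcond=1e-8) / tau_s + np.eye(3) / tau_v
    prec = np.linalg.inv(sigma)
    g = np.linspace(-5.0, 5.0, 81)
    e1, e2, e3 = np.meshgrid(g, g, g, indexing="ij")
    eta = np.stack([e1, e2, e3], axis=-1)
    logp = -0.5 * np.einsum("...i,ij,...j->...", eta, prec, eta)
    for j, d in enumerate(nodes):
        s, n = counts[d]
        logp += s * eta[..., j] - n * np.logaddexp(0, eta[..., j])
    w = np.exp(logp - logp.max())
    oracle_p = np.array([(expit(eta[..., j]) * w).sum() / w.sum() for j in range(3)])
    return float(np.abs(mcmc_p - oracle_p).max())


# ---------------------------------------------------------------------------
# replicate studies


def _recovery_scenario(seed: int) -> synthetic.ScenarioConfig:
    # n ~ 5,000 women in 60 districts with identifiable spatial variation;
    # displacement off so assignment is exact and only inference is probed
    return synthetic.ScenarioConfig(
        n_districts_rows=6, n_districts_cols=10, n_clusters=180,
        women_per_cluster_mean=28, tau_struc=3.0, tau_unstruc=12.5,
        displacement_on=False, seed=seed,
    )


def recovery_and_coverage_study(
    n_replicates: int = 50,
    seed: int = 0,
    n_iter: int = 4000,
    n_burnin: int = 1200,
    n_thin: int = 1,
    beta_replicates: int = 20,
) -> dict:
    """Replicate simulation study at known (beta, tau).

    Returns per-coefficient counts of true-beta-in-95%-interval over the
    first ``beta_replicates`` replicates, pooled district-interval coverage
    over all replicates, and the pooled Spearman correlation between a
    district's sample size and its interval width.
    """
    beta_hits: dict[str, int] = {}
    dist_hits = dist_total = 0
    n_women_all: list[int] = []
    widths_all: list[float] = []
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 10, size=n_replicates)
    for r, rep_seed in enumerate(rep_seeds):
        cfg = _recovery_scenario(int(rep_seed))
        dmap = synthetic.generate_district_lattice(
            cfg.n_districts_rows, cfg.n_districts_cols, cfg.cell_size_km)
        adj = geo.build_adjacency(dmap)
        ds = synthetic.generate_survey(cfg, dmap, adj)
        assignment = dict(ds.truth.cluster_district)
        spec = bym.ModelSpec(sampler=bym.SamplerSettings(
            n_iter=n_iter, n_burnin=n_burnin, n_thin=n_thin, seed=int(rep_seed) + 1))
        design = bym.build_design(ds, spec, assignment)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = bym.fit_model(spec, design, adj)

        if r < beta_replicates:
            # generator beta keys match the design's dummy column names;
            # the <20 model's true intercept is the age-20 cutpoint
            truth_by_name = {"intercept": ds.truth.alpha[2], **ds.truth.beta}
            for c, name in enumerate(fit.beta_names):
                true_val = truth_by_name.get(name)
                if true_val is None:
                    continue
                lo, hi = np.quantile(fit.beta[:, c], [0.025, 0.975])
                beta_hits.setdefault(name, 0)
                beta_hits[name] += int(lo <= true_val <= hi)

        ests = mapping.predict_district_prevalence(fit, design)
        p_true = _true_district_prevalence(ds, cfg)
        for e in ests:
            if e.district_id not in p_true:
                continue
            dist_hits += int(e.q025 <= p_true[e.district_id] <= e.q975)
            dist_total += 1
            n_women_all.append(e.n_women)
            widths_all.append(e.ci_width)
    rho = float(spearmanr(n_women_all, widths_all).statistic)
    return {
        "beta_hits": beta_hits,
        "beta_replicates": beta_replicates,
        "district_coverage": dist_hits / dist_total,
        "district_total": dist_total,
        "n_women": sum(1 for _ in n_women_all),
        "spearman_n_vs_width": rho,
    }


def _true_district_prevalence(ds: synthetic.SurveyDataset, cfg: synthetic.ScenarioConfig) -> dict[str, float]:
    """Expected <20 prevalence per district given the realised effects and
    the realised covariate composition of the women truly living there."""
    df = ds.records_frame()
    tru = ds.truth
    fsp = tru.f_struc + tru.f_unstruc
    eta = np.where(df["urban"], cfg.beta.get("urban", 0.0), 0.0)
    eta = eta + df["education"].map(lambda e: cfg.beta.get(f"education:{e}", 0.0)).to_numpy()
    eta = eta + df["wealth_quintile"].map(lambda q: cfg.beta.get(f"wealth:{q}", 0.0)).to_numpy()
    dist = df["cluster_id"].map(tru.cluster_district)
    out = {}
    for j, d in enumerate(tru.district_ids):
        m = (dist == d).to_numpy()
        if m.sum() == 0:
            continue
        out[d] = float(expit(tru.alpha[2] + eta[m] + fsp[j]).mean())
    return out


def dic_direction_study(
    n_replicates: int = 20,
    seed: int = 0,
    n_iter: int = 5000,
    n_burnin: int = 1500,
) -> dict:
    """BYM vs Besag-only DIC on data with genuine iid district heterogeneity
    (no structured component, effect SD 1): counts replicates where the BYM
    model attains the lower DIC."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 10, size=n_replicates)
    wins = 0
    diffs = []
    for rep_seed in rep_seeds:
        cfg = synthetic.ScenarioConfig(
            n_districts_rows=10, n_districts_cols=10, n_clusters=200,
            women_per_cluster_mean=25, tau_struc=1e6, tau_unstruc=1.0,
            displacement_on=False, seed=int(rep_seed),
        )
        dmap = synthetic.generate_district_lattice(10, 10, cfg.cell_size_km)
        adj = geo.build_adjacency(dmap)
        ds = synthetic.generate_survey(cfg, dmap, adj)
        assignment = dict(ds.truth.cluster_district)
        dic = {}
        for structure in ("besag", "bym"):
            spec = bym.ModelSpec(spatial=structure, sampler=bym.SamplerSettings(
                n_iter=n_iter, n_burnin=n_burnin, n_thin=1, seed=int(rep_seed) + 7))
            design = bym.build_design(ds, spec, assignment)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = bym.fit_model(spec, design, adj)
            dic[structure] = selection.compute_dic(fit, design, label=structure).dic
        diffs.append(dic["bym"] - dic["besag"])
        wins += int(dic["bym"] < dic["besag"])
    return {"bym_wins": wins, "n_replicates": n_replicates, "dic_differences": diffs}


def mll_toy_errors(seed: int = 0) -> dict[str, float]:
    """Thermodynamic-integration evidence vs closed forms on two toys."""
    def bern_ll(th):
        return float(np.log(expit(th[0])))

    def bern_lp(th):
        return float(np.log(expit(th[0])) + np.log(expit(-th[0])))

    mll_b, _ = selection.thermodynamic_mll_generic(
        bern_ll, bern_lp, np.zeros(1), selection.default_ladder(21),
        n_iter=4000, n_burnin=1000, seed=seed + 4)
    bernoulli_err = abs(mll_b - np.log(0.5))

    n_tr, y_obs = 20, 7
    log_binom = gammaln(n_tr + 1) - gammaln(y_obs + 1) - gammaln(n_tr - y_obs + 1)

    def bb_ll(th):
        p = expit(th[0])
        return float(log_binom + y_obs * np.log(p) + (n_tr - y_obs) * np.log1p(-p))

    def bb_lp(th):
        p = expit(th[0])
        return float(-betaln(2, 2) + 2 * np.log(p) + 2 * np.log1p(-p))

    closed = float(log_binom + betaln(2 + y_obs, 2 + n_tr - y_obs) - betaln(2, 2))
    mll_bb, _ = selection.thermodynamic_mll_generic(
        bb_ll, bb_lp, np.zeros(1), selection.default_ladder(21),
        n_iter=4000, n_burnin=1000, seed=seed + 9)
    return {"bernoulli_abs_err": float(bernoulli_err),
            "beta_binomial_abs_err": float(abs(mll_bb - closed))}


def geo_overlap_study(n_configs: int = 20, seed: int = 2024) -> dict:
    """Geometric disc/district overlap vs the grid-sampling oracle on random
    border configurations; returns the worst discrepancy relative to disc
    area and whether every greatest-overlap winner agrees."""
    from shapely.geometry import Point

    dmap = synthetic.generate_district_lattice(3, 3, 10.0)
    rng = np.random.default_rng(seed)
    worst = 0.0
    winners_agree = True
    for _ in range(n_configs):
        x = float(rng.uniform(2000, 28_000))
        y = float(rng.uniform(2000, 28_000))
        urban = bool(rng.integers(2))
        radius = 2000.0 if urban else 5000.0
        disc_area = np.pi * radius**2
        disc = Point(x, y).buffer(radius, quad_segs=64)
        exact_areas, grid_areas = {}, {}
        for d in dmap.districts:
            exact_areas[d.district_id] = disc.intersection(d.polygon).area
            grid_areas[d.district_id] = geo.disc_polygon_overlap_grid(x, y, radius, d.polygon)
            worst = max(worst, abs(exact_areas[d.district_id] - grid_areas[d.district_id]) / disc_area)
        if max(exact_areas, key=exact_areas.get) != max(grid_areas, key=grid_areas.get):
            winners_agree = False
    return {"max_rel_discrepancy": float(worst), "winners_agree": winners_agree,
            "n_configs": n_configs}


def determinism_check(seed: int = 0) -> bool:
    """Same config + seed twice: byte-identical CSVs, identical draws and
    identical GeoJSON properties."""
    import json as _json
    import tempfile
    from pathlib import Path

    cfg = synthetic.ScenarioConfig(n_clusters=50, women_per_cluster_mean=10, seed=seed)
    dmap = synthetic.generate_district_lattice(cfg.n_districts_rows, cfg.n_districts_cols, cfg.cell_size_km)
    adj = geo.build_adjacency(dmap)
    outputs = []
    with tempfile.TemporaryDirectory() as td:
        for run in ("a", "b"):
            ds = synthetic.generate_survey(cfg, dmap, adj)
            d = Path(td) / run
            ds.to_csv(d)
            assignment = geo.assign_clusters(ds.clusters, dmap)
            spec = bym.ModelSpec(sampler=bym.SamplerSettings(
                n_iter=400, n_burnin=100, n_thin=1, seed=seed + 1))
            design = bym.build_design(ds, spec, assignment)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = bym.fit_model(spec, design, adj)
            ests = mapping.predict_district_prevalence(fit, design)
            gj = d / "map.geojson"
            mapping.export_choropleth(dmap, ests, gj)
            outputs.append((
                (d / "records.csv").read_bytes(),
                fit.beta.tobytes(),
                _json.loads(gj.read_text()),
            ))
    return outputs[0] == outputs[1]
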
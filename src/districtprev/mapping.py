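"""District-level predicted prevalence, uncertainty summaries and choropleths.

For each posterior draw the predicted prevalence of district j is the
average of logistic(x_i' beta + f_spat(j)) over the women sampled in j
(the observed within-district covariate composition).  Districts with no
sampled women fall back to the study-wide composition combined with their
own spatial effect, and are flagged.  Summarising the per-draw prevalences
gives a posterior mean, SD and equal-tailed 95% credible interval per
district; the interval width is the map-level uncertainty measure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import bym, geo, selection, synthetic, tabulate

log = logging.getLogger(__name__)


@dataclass
class DistrictEstimate:
    district_id: str
    mean: float
    sd: float
    q025: float
    q975: float
    ci_width: float
    n_women: int
    extrapolated: bool = False  # no sampled women; national composition used

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (-eps <= self.q025 <= self.q975 <= 1 + eps):
            raise ValueError(f"invalid credible bounds for {self.district_id}")
        if self.ci_width > 1 + eps:
            raise ValueError("credible interval width exceeds 1")


def _district_draw_matrix(
    fit: bym.PosteriorFit,
    design: bym.DesignMatrix,
    profile: Literal["observed", "national", "reference"] = "observed",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-draw, per-district predicted prevalence.

    Returns (draws S x J, n_women per district, extrapolated flags).
    """
    node_pos = {n: i for i, n in enumerate(fit.district_order)}
    dist_idx = np.array([node_pos[d] for d in design.district_ids])
    J = len(fit.district_order)
    S = fit.n_draws
    f = fit.f_spat()  # (S, J)
    eta_fixed = design.X @ fit.beta.T  # (n, S)
    n_women = np.bincount(dist_idx, minlength=J)
    out = np.empty((S, J))
    for j in range(J):
        rows = np.flatnonzero(dist_idx == j)
        if profile == "reference":
            eta = fit.beta[:, 0][None, :]  # intercept only
        elif profile == "national" or rows.size == 0:
            eta = eta_fixed
        else:
            eta = eta_fixed[rows]
        out[:, j] = expit(eta + f[:, j][None, :]).mean(axis=0)
    return out, n_women, n_women == 0


def predict_district_prevalence(
    fit: bym.PosteriorFit,
    design: bym.DesignMatrix,
    district_id: str | None = None,
    profile: Literal["observed", "national", "reference"] = "observed",
) -> DistrictEstimate | list[DistrictEstimate]:
    """Posterior district prevalence estimate(s) with 95% credible interval.

    With ``district_id`` None, returns estimates for every district in the
    fit's adjacency order.
    """
    draws, n_women, extrap = _district_draw_matrix(fit, design, profile)
    estimates = []
    for j, did in enumerate(fit.district_order):
        s = bym.posterior_summary(draws[:, j])
        estimates.append(
            DistrictEstimate(
                district_id=did,
                mean=s.mean,
                sd=s.sd,
                q025=s.q025,
                q975=s.q975,
                ci_width=s.ci_width,
                n_women=int(n_women[j]),
                extrapolated=bool(extrap[j]),
            )
        )
    if district_id is None:
        return estimates
    for e in estimates:
        if e.district_id == district_id:
            return e
    raise KeyError(district_id)


def summarize_sd_distribution(estimates: Sequence[DistrictEstimate]) -> dict[str, float]:
    """Six-number summary (min, q1, median, mean, q3, max) of district SDs.

    Quartiles use linear interpolation on the sorted SDs.
    """
    if len(estimates) == 0:
        raise ValueError("no district estimates supplied")
    sds = np.array([e.sd for e in estimates])
    return {
        "min": float(sds.min()),
        "q1": float(np.quantile(sds, 0.25)),
        "median": float(np.quantile(sds, 0.5)),
        "mean": float(sds.mean()),
        "q3": float(np.quantile(sds, 0.75)),
        "max": float(sds.max()),
    }


def _bin_labels(values: np.ndarray, bins: Literal["quantile", "fixed"], edges: Sequence[float] | None, n_bins: int) -> list[str]:
    if bins == "quantile":
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        idx = np.clip(np.searchsorted(qs, values, side="right") - 1, 0, n_bins - 1)
        return [f"Q{i + 1}" for i in idx]
    if edges is None:
        raise ValueError("fixed binning requires explicit edges")
    labels = []
    for v in values:
        if v < edges[0]:
            labels.append("underflow")
        elif v >= edges[-1]:
            labels.append("overflow")
        else:
            i = int(np.searchsorted(edges, v, side="right") - 1)
            labels.append(f"[{edges[i]:g},{edges[i + 1]:g})")
    return labels


def export_choropleth(
    dmap: geo.DistrictMap,
    estimates: Sequence[DistrictEstimate],
    path: str | Path,
    bins: Literal["quantile", "fixed"] = "quantile",
    n_bins: int = 5,
    fixed_edges: Sequence[float] | None = None,
    render_png: str | Path | None = None,
) -> None:
    """Write a GeoJSON choropleth with mean/sd/ci_width/bin properties.

    Values outside explicit fixed bins land in labelled overflow/underflow
    bins rather than being clamped.  A companion uncertainty layer (binned
    on ci_width) is written alongside with suffix ``_uncertainty``.
    """
    by_id = {e.district_id: e for e in estimates}
    missing = sorted(set(dmap.ids) - set(by_id))
    if missing:
        raise ValueError(f"no estimate for districts: {missing}")
    means = np.array([by_id[i].mean for i in dmap.ids])
    widths = np.array([by_id[i].ci_width for i in dmap.ids])
    mean_bins = _bin_labels(means, bins, fixed_edges, n_bins)
    width_bins = _bin_labels(widths, "quantile", None, n_bins)
    props = {}
    for i, did in enumerate(dmap.ids):
        e = by_id[did]
        props[did] = {
            "mean": e.mean,
            "sd": e.sd,
            "q025": e.q025,
            "q975": e.q975,
            "ci_width": e.ci_width,
            "n_women": e.n_women,
            "extrapolated": e.extrapolated,
            "bin": mean_bins[i],
            "ci_width_bin": width_bins[i],
        }
    dmap.to_geojson(path, extra_properties=props)
    unc_path = Path(path).with_name(Path(path).stem + "_uncertainty.geojson")
    unc_props = {d: {"ci_width": props[d]["ci_width"], "bin": props[d]["ci_width_bin"]} for d in dmap.ids}
    dmap.to_geojson(unc_path, extra_properties=unc_props)
    if render_png is not None:
        _render_png(dmap, means, widths, render_png)


def _render_png(dmap: geo.DistrictMap, means: np.ndarray, widths: np.ndarray, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    fig, axes = plt.subplots(1, 2, figsize=(12, 5))
    for ax, vals, title in ((axes[0], means, "posterior mean prevalence"),
                            (axes[1], widths, "95% CrI width")):
        patches = []
        for d in dmap.districts:
            geoms = getattr(d.polygon, "geoms", [d.polygon])
            for g in geoms:
                patches.append(MplPolygon(np.asarray(g.exterior.coords)))
        pc = PatchCollection(patches, cmap="viridis", edgecolor="white", linewidth=0.3)
        pc.set_array(np.repeat(vals, [len(getattr(d.polygon, "geoms", [0])) for d in dmap.districts]))
        ax.add_collection(pc)
        ax.autoscale()
        ax.set_aspect("equal")
        ax.set_title(title)
        fig.colorbar(pc, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline orchestration


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> Path:
    """End-to-end run: simulate/ingest -> tabulate -> fit -> compare -> map.

    The YAML config needs either a ``simulate`` block (ScenarioConfig
    fields) or ``inputs`` paths; sampler settings and the bracket/structure
    grid are optional overrides.  Writes tables, draws summaries, GeoJSON
    maps and a manifest with seeds and content hashes.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict) or ("simulate" not in cfg and "inputs" not in cfg):
        raise ValueError("pipeline config must contain a 'simulate' or 'inputs' block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": None}
    t_start = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise PipelineError(name, exc) from exc
            manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 2)})
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return result

        return deco

    sampler_cfg = cfg.get("sampler", {})
    brackets = cfg.get("brackets", ["lt16", "16to17", "18to19", "lt20"])
    structures = cfg.get("structures", ["besag", "bym"])

    @stage("simulate")
    def _sim():
        if "simulate" in cfg:
            sc = synthetic.ScenarioConfig(**cfg["simulate"])
            manifest["seed"] = sc.seed
            dmap = synthetic.generate_district_lattice(
                sc.n_districts_rows, sc.n_districts_cols, sc.cell_size_km
            )
            adj = geo.build_adjacency(dmap, cfg.get("contiguity", "queen"))
            ds = synthetic.generate_survey(sc, dmap, adj)
            ds.to_csv(out / "data")
            dmap.to_geojson(out / "data" / "districts.geojson")
            return ds, dmap, adj
        paths = cfg["inputs"]
        dmap = geo.read_district_geometries(paths["districts"])
        adj = geo.build_adjacency(dmap, cfg.get("contiguity", "queen"))
        ds = synthetic.SurveyDataset.from_csv(paths["data_dir"])
        return ds, dmap, adj

    dataset, dmap, adj = _sim

    @stage("geoprep")
    def _assign():
        assignment = geo.assign_clusters(dataset.clusters, dmap)
        pd.Series(assignment, name="district_id").rename_axis("cluster_id").to_csv(
            out / "cluster_assignment.csv", lineterminator="\n"
        )
        adj.to_edge_csv(out / "adjacency.csv")
        return assignment

    assignment = _assign

    @stage("tabulate")
    def _tab():
        tables = {}
        for strat in ("total", "residence", "education", "wealth_quintile"):
            t = tabulate.weighted_prevalence(dataset, strat)
            t.to_csv(out / f"prevalence_{strat}.csv")
            tables[strat] = t
        return tables

    _tab

    seed0 = manifest.get("seed") or cfg.get("seed", 0)
    fits: dict[tuple[str, str], bym.PosteriorFit] = {}
    designs: dict[str, bym.DesignMatrix] = {}

    @stage("fit")
    def _fit():
        settings = bym.SamplerSettings(
            n_iter=sampler_cfg.get("n_iter", 20_000),
            n_burnin=sampler_cfg.get("n_burnin", 5_000),
            n_thin=sampler_cfg.get("n_thin", 5),
            seed=sampler_cfg.get("seed", seed0),
        )
        for bi, bracket in enumerate(brackets):
            spec = bym.ModelSpec(bracket=bracket, sampler=replace(settings, seed=settings.seed + bi))
            designs[bracket] = bym.build_design(dataset, spec, assignment)
            for structure in structures:
                s = replace(spec, spatial=structure)
                fits[(bracket, structure)] = bym.fit_model(s, designs[bracket], adj)

    _fit

    @stage("compare")
    def _compare():
        diags = []
        for (bracket, structure), fit in fits.items():
            d = selection.compute_dic(fit, designs[bracket], label=f"{bracket}/{structure}")
            diags.append(d)
        table = selection.compare_models(diags)
        table.to_csv(out / "model_comparison.csv", index=False, lineterminator="\n")
        return table

    _compare

    @stage("map")
    def _map():
        structure = "bym" if "bym" in structures else structures[0]
        sd_rows = {}
        for bracket in brackets:
            fit = fits[(bracket, structure)]
            ests = predict_district_prevalence(fit, designs[bracket])
            pd.DataFrame([asdict(e) for e in ests]).to_csv(
                out / f"district_estimates_{bracket}.csv", index=False, lineterminator="\n"
            )
            export_choropleth(dmap, ests, out / f"map_{bracket}.geojson")
            sd_rows[bracket] = summarize_sd_distribution(ests)
        pd.DataFrame(sd_rows).T.to_csv(out / "sd_distribution.csv", lineterminator="\n")

    _map

    manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
    manifest["hashes"] = {
        p.name: _sha256(p) for p in sorted(out.rglob("*")) if p.is_file() and p.suffix in {".csv", ".geojson", ".json"}
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
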
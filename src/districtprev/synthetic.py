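"""Seeded generator of DHS-like surveys for district-level prevalence modelling.

The generator emulates the structure of a two-stage cluster survey of women
aged 20-29: ~75 districts, ~289 clusters with (displaced) planar GPS
coordinates, ~4,400 women with urban/rural residence, education, wealth
quintile, a sampling weight and an age at first birth (or none).  Outcomes
are driven by a logistic model on the covariates plus a district-level
spatial effect that decomposes into a structured (intrinsic CAR) and an
unstructured (i.i.d. Gaussian) part — the same generative family the
downstream Besag/BYM fits assume.

Age at first birth is drawn once per woman as a categorical over the
brackets <16, 16-17, 18-19, >=20/none with cumulative probabilities
``logistic(alpha_a + eta)`` at cut ages a in {16, 18, 20}; the bracket
indicators are therefore additive by construction and the <20 outcome is
exactly logistic in ``eta``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from shapely.geometry import Point

from .geo import AdjacencyGraph, District, DistrictMap, build_adjacency

EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")
WEALTH_QUINTILES = (1, 2, 3, 4, 5)

# Default covariate mix and log-odds contrasts, chosen once to mirror the
# magnitude of the socioeconomic gradients a national survey of this kind
# reports (rural, no-education, lowest-quintile reference levels).
DEFAULT_EDU_PROBS = {"none": 0.28, "primary": 0.20, "secondary": 0.39, "higher": 0.13}
DEFAULT_WEALTH_PROBS = {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2}
DEFAULT_BETA = {
    "urban": -0.52,
    "education:primary": -0.52,
    "education:secondary": -1.17,
    "education:higher": -3.50,
    "wealth:2": -0.25,
    "wealth:3": -0.44,
    "wealth:4": -0.73,
    "wealth:5": -1.38,
}
# Cumulative first-birth prevalence targets at ages <16, <18, <20 used to
# calibrate the cut-point intercepts of the default scenario.
DEFAULT_CUM_TARGETS = (0.048, 0.212, 0.433)


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic-survey scenario.

    ``beta`` maps covariate levels to log-odds contrasts against the
    reference levels (rural / no education / lowest quintile); ``alpha``
    holds the three cut-point intercepts at ages 16, 18, 20 and is
    calibrated to ``cum_targets`` when left unset.
    """

    n_districts_rows: int = 5
    n_districts_cols: int = 15
    cell_size_km: float = 30.0
    n_clusters: int = 289
    women_per_cluster_mean: float = 15.3
    urban_fraction: float = 0.3
    beta0: float | None = None  # alias for alpha[2] when only <20 is modelled
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    alpha: tuple[float, float, float] | None = None
    cum_targets: tuple[float, float, float] = DEFAULT_CUM_TARGETS
    edu_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EDU_PROBS))
    wealth_probs: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_WEALTH_PROBS))
    # Defaults give a combined district-effect SD near 0.45 on the log-odds
    # scale (structured variance ~0.12 on the default lattice, unstructured
    # 0.08), matching the magnitude of between-district prevalence spread
    # that national surveys of adolescent first births exhibit.
    tau_struc: float = 3.0
    tau_unstruc: float = 12.5
    displacement_on: bool = True
    rural_far_displacement: bool = False  # 1% of rural points moved up to 10 km
    heterogeneous_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_districts_rows < 1 or self.n_districts_cols < 1:
            raise ScenarioError("grid dimensions must be >= 1")
        if self.cell_size_km <= 0:
            raise ScenarioError("cell size must be positive")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ScenarioError("urban_fraction must lie in [0, 1]")
        if self.tau_struc <= 0 or self.tau_unstruc <= 0:
            raise ScenarioError("precisions must be strictly positive")
        if self.n_clusters < 1 or self.women_per_cluster_mean <= 0:
            raise ScenarioError("cluster counts must be positive")
        for probs, dom in ((self.edu_probs, EDUCATION_LEVELS), (self.wealth_probs, WEALTH_QUINTILES)):
            if set(probs) != set(dom):
                raise ScenarioError(f"category probabilities must cover {dom}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ScenarioError("category probabilities must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["wealth_probs"] = {str(k): v for k, v in d["wealth_probs"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "wealth_probs" in d:
            d["wealth_probs"] = {int(k): v for k, v in d["wealth_probs"].items()}
        if d.get("alpha") is not None:
            d["alpha"] = tuple(d["alpha"])
        d["cum_targets"] = tuple(d.get("cum_targets", DEFAULT_CUM_TARGETS))
        return cls(**d)


@dataclass
class ClusterSite:
    cluster_id: str
    x_m: float
    y_m: float
    urban: bool
    displaced_x_m: float
    displaced_y_m: float


@dataclass
class WomanRecord:
    woman_id: str
    cluster_id: str
    age_at_survey: int
    age_first_birth: int | None
    urban: bool
    education: str
    wealth_quintile: int
    weight: float


@dataclass
class TruthBundle:
    beta: dict[str, float]
    alpha: tuple[float, float, float]
    f_struc: np.ndarray
    f_unstruc: np.ndarray
    district_ids: list[str]
    cluster_district: dict[str, str]


@dataclass
class SurveyDataset:
    records: list[WomanRecord]
    clusters: list[ClusterSite]
    truth: TruthBundle | None = None

    def __post_init__(self) -> None:
        known = {c.cluster_id for c in self.clusters}
        for r in self.records:
            if r.cluster_id not in known:
                raise ScenarioError(f"record {r.woman_id} references unknown cluster {r.cluster_id}")
            if r.weight <= 0:
                raise ScenarioError(f"record {r.woman_id} has non-positive weight")

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "woman_id": [r.woman_id for r in self.records],
                "cluster_id": [r.cluster_id for r in self.records],
                "age_at_survey": [r.age_at_survey for r in self.records],
                "age_first_birth": [r.age_first_birth for r in self.records],
                "urban": [r.urban for r in self.records],
                "education": [r.education for r in self.records],
                "wealth_quintile": [r.wealth_quintile for r in self.records],
                "weight": [r.weight for r in self.records],
            }
        )

    def clusters_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [c.cluster_id for c in self.clusters],
                "x_m": [c.x_m for c in self.clusters],
                "y_m": [c.y_m for c in self.clusters],
                "urban": [c.urban for c in self.clusters],
                "displaced_x_m": [c.displaced_x_m for c in self.clusters],
                "displaced_y_m": [c.displaced_y_m for c in self.clusters],
            }
        )

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rec = self.records_frame()
        rec["age_first_birth"] = rec["age_first_birth"].astype("Int64")
        buf = io.StringIO()
        rec.to_csv(buf, index=False, lineterminator="\n")
        (out / "records.csv").write_text(buf.getvalue())
        buf = io.StringIO()
        self.clusters_frame().to_csv(buf, index=False, lineterminator="\n")
        (out / "clusters.csv").write_text(buf.getvalue())
        if self.truth is not None:
            truth = {
                "beta": self.truth.beta,
                "alpha": list(self.truth.alpha),
                "district_ids": self.truth.district_ids,
                "f_struc": self.truth.f_struc.tolist(),
                "f_unstruc": self.truth.f_unstruc.tolist(),
                "cluster_district": self.truth.cluster_district,
            }
            (out / "truth.json").write_text(json.dumps(truth, sort_keys=True))

    @classmethod
    def from_csv(cls, out_dir: str | Path) -> "SurveyDataset":
        out = Path(out_dir)
        rec = pd.read_csv(out / "records.csv")
        clu = pd.read_csv(out / "clusters.csv")
        records = [
            WomanRecord(
                woman_id=str(r.woman_id),
                cluster_id=str(r.cluster_id),
                age_at_survey=int(r.age_at_survey),
                age_first_birth=None if pd.isna(r.age_first_birth) else int(r.age_first_birth),
                urban=bool(r.urban),
                education=str(r.education),
                wealth_quintile=int(r.wealth_quintile),
                weight=float(r.weight),
            )
            for r in rec.itertuples()
        ]
        clusters = [
            ClusterSite(str(c.cluster_id), float(c.x_m), float(c.y_m), bool(c.urban),
                        float(c.displaced_x_m), float(c.displaced_y_m))
            for c in clu.itertuples()
        ]
        return cls(records=records, clusters=clusters)


def generate_district_lattice(n_rows: int, n_cols: int, cell_size_km: float) -> DistrictMap:
    """Square-cell district lattice on the plane (ids ``d001``, ``d002``, ...)."""
    if n_rows < 1 or n_cols < 1 or cell_size_km <= 0:
        raise ScenarioError("lattice dimensions and cell size must be positive")
    from shapely.geometry import box

    size = cell_size_km * 1000.0
    districts = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            k += 1
            districts.append(
                District(
                    district_id=f"d{k:03d}",
                    polygon=box(c * size, r * size, (c + 1) * size, (r + 1) * size),
                    name=f"district {k}",
                )
            )
    return DistrictMap(districts)


def sample_spatial_effects(
    adjacency: AdjacencyGraph,
    tau_struc: float,
    tau_unstruc: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (f_struc, f_unstruc) pair for the districts of ``adjacency``.

    f_struc comes from the intrinsic CAR distribution with precision
    ``tau_struc * (D - W)``, sampled exactly per connected component via the
    eigendecomposition of the component Laplacian with the null space (the
    component-constant direction) excluded — so the sum-to-zero constraint
    holds by construction.  Isolated districts get f_struc = 0.
    """
    if tau_struc <= 0 or tau_unstruc <= 0:
        raise ValueError("precisions must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = adjacency.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    q = adjacency.laplacian()
    f_struc = np.zeros(len(nodes))
    for comp in adjacency.components():
        ii = np.array([idx[n] for n in comp])
        if len(ii) == 1:
            continue
        qc = q[np.ix_(ii, ii)]
        evals, evecs = np.linalg.eigh(qc)
        keep = evals > 1e-10 * evals.max()
        z = rng.standard_normal(int(keep.sum()))
        f_struc[ii] = evecs[:, keep] @ (z / np.sqrt(tau_struc * evals[keep]))
    f_unstruc = rng.standard_normal(len(nodes)) / np.sqrt(tau_unstruc)
    return f_struc, f_unstruc


def _marginal_spatial_variance(adjacency: AdjacencyGraph, tau_struc: float, tau_unstruc: float) -> float:
    """Average marginal variance of f_struc + f_unstruc across districts."""
    q = adjacency.laplacian()
    # generous rcond: the Laplacian's null eigenvalue is only ~1e-15 numerically
    var_struc = (
        float(np.mean(np.diag(np.linalg.pinv(q, rcond=1e-8, hermitian=True)))) / tau_struc
        if len(q) > 1
        else 0.0
    )
    return var_struc + 1.0 / tau_unstruc


def calibrate_cutpoints(config: ScenarioConfig, adjacency: AdjacencyGraph) -> tuple[float, float, float]:
    """Solve for the cut-point intercepts matching the cumulative targets.

    Marginalises the logistic link over the configured covariate mix
    (enumerated exactly) and the spatial-effect distribution (Gauss-Hermite
    quadrature over a normal approximation with the ICAR+iid marginal
    variance), then root-finds each alpha so the population prevalence of a
    first birth before the cut age equals its target.
    """
    combos, probs = [], []
    for urb, p_u in ((True, config.urban_fraction), (False, 1 - config.urban_fraction)):
        for edu, p_e in config.edu_probs.items():
            for wq, p_w in config.wealth_probs.items():
                eta = 0.0
                if urb:
                    eta += config.beta.get("urban", 0.0)
                eta += config.beta.get(f"education:{edu}", 0.0)
                eta += config.beta.get(f"wealth:{wq}", 0.0)
                combos.append(eta)
                probs.append(p_u * p_e * p_w)
    combos = np.array(combos)
    probs = np.array(probs)
    var = _marginal_spatial_variance(adjacency, config.tau_struc, config.tau_unstruc)
    nodes_gh, w_gh = np.polynomial.hermite_e.hermegauss(31)
    spat = nodes_gh * np.sqrt(var)
    w_gh = w_gh / w_gh.sum()

    def marginal_prev(alpha: float) -> float:
        grid = alpha + combos[:, None] + spat[None, :]
        return float(probs @ expit(grid) @ w_gh)

    alphas = []
    for target in config.cum_targets:
        alphas.append(brentq(lambda a: marginal_prev(a) - target, -30, 30, xtol=1e-10))
    a = tuple(alphas)
    if not (a[0] < a[1] < a[2]):
        raise ScenarioError(f"calibrated cutpoints not increasing: {a}")
    return a


def generate_survey(
    config: ScenarioConfig,
    district_map: DistrictMap,
    adjacency: AdjacencyGraph | None = None,
) -> SurveyDataset:
    """Generate a full synthetic survey under ``config`` on ``district_map``.

    Deterministic given (config, seed): identical inputs yield byte-identical
    CSV/GeoJSON output.
    """
    if len(district_map) == 0:
        raise ScenarioError("district map is empty")
    rng = np.random.default_rng(config.seed)
    if adjacency is None:
        adjacency = build_adjacency(district_map, "queen")
    ids = district_map.ids
    f_struc, f_unstruc = sample_spatial_effects(adjacency, config.tau_struc, config.tau_unstruc, rng)
    f_spat = f_struc + f_unstruc

    if config.alpha is not None:
        alpha = tuple(config.alpha)
    elif config.beta0 is not None:
        alpha = (config.beta0 - 3.0, config.beta0 - 1.5, config.beta0)
    else:
        alpha = calibrate_cutpoints(config, adjacency)

    # clusters: district chosen proportional to area, point uniform in cell
    areas = np.array([d.polygon.area for d in district_map.districts])
    cluster_district_idx = rng.choice(len(ids), size=config.n_clusters, p=areas / areas.sum())
    clusters: list[ClusterSite] = []
    cluster_district: dict[str, str] = {}
    for k, di in enumerate(cluster_district_idx):
        poly = district_map.districts[di].polygon
        minx, miny, maxx, maxy = poly.bounds
        while True:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if poly.contains(Point(x, y)):
                break
        urban = bool(rng.uniform() < config.urban_fraction)
        dx, dy = x, y
        if config.displacement_on:
            cap = 2000.0 if urban else 5000.0
            if not urban and config.rural_far_displacement and rng.uniform() < 0.01:
                cap = 10000.0
            theta = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0, cap)
            dx, dy = x + r * np.cos(theta), y + r * np.sin(theta)
        cid = f"c{k + 1:04d}"
        clusters.append(ClusterSite(cid, x, y, urban, dx, dy))
        cluster_district[cid] = ids[di]

    # cluster-level weight factors (two-stage scheme, optional)
    if config.heterogeneous_weights:
        cluster_factor = rng.lognormal(0.0, 0.3, size=config.n_clusters)
        strata_factor = np.where([c.urban for c in clusters], 0.7, 1.1)
        cluster_weight = cluster_factor * strata_factor
        cluster_weight /= cluster_weight.mean()
    else:
        cluster_weight = np.ones(config.n_clusters)

    records: list[WomanRecord] = []
    edu_levels = list(EDUCATION_LEVELS)
    edu_p = np.array([config.edu_probs[e] for e in edu_levels])
    wq_p = np.array([config.wealth_probs[q] for q in WEALTH_QUINTILES])
    widx = 0
    for k, c in enumerate(clusters):
        n_w = max(1, int(rng.poisson(config.women_per_cluster_mean)))
        di = ids.index(cluster_district[c.cluster_id])
        for _ in range(n_w):
            widx += 1
            edu = edu_levels[rng.choice(4, p=edu_p)]
            wq = int(WEALTH_QUINTILES[rng.choice(5, p=wq_p)])
            eta = f_spat[di]
            if c.urban:
                eta += config.beta.get("urban", 0.0)
            eta += config.beta.get(f"education:{edu}", 0.0)
            eta += config.beta.get(f"wealth:{wq}", 0.0)
            cum = expit(np.array(alpha) + eta)  # P(afb<16), P(afb<18), P(afb<20)
            u = rng.uniform()
            if u < cum[0]:
                afb = int(rng.integers(13, 16))
            elif u < cum[1]:
                afb = int(rng.integers(16, 18))
            elif u < cum[2]:
                afb = int(rng.integers(18, 20))
            else:
                afb = None
            records.append(
                WomanRecord(
                    woman_id=f"w{widx:05d}",
                    cluster_id=c.cluster_id,
                    age_at_survey=int(rng.integers(20, 30)),
                    age_first_birth=afb,
                    urban=c.urban,
                    education=edu,
                    wealth_quintile=wq,
                    weight=float(cluster_weight[k]),
                )
            )

    truth = TruthBundle(
        beta=dict(config.beta),
        alpha=alpha,
        f_struc=f_struc,
        f_unstruc=f_unstruc,
        district_ids=list(ids),
        cluster_district=cluster_district,
    )
    return SurveyDataset(records=records, clusters=clusters, truth=truth)
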
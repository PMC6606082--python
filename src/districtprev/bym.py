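"""Bayesian spatial logistic regression for district-level prevalence.

Model, for woman i in district j:

    y_ij ~ Bernoulli(p_ij)
    logit(p_ij) = x_ij' beta + f_spat(j)
    f_spat(j)   = f_struc(j) + f_unstruc(j)

with f_struc an intrinsic CAR (Besag) field over the district contiguity
graph — precision tau_struc * (D - W), identified by a per-component
sum-to-zero constraint — and f_unstruc i.i.d. Normal(0, 1/tau_unstruc).
``besag`` keeps only the structured field, ``none`` drops both.

Inference is exact MCMC via Pólya-Gamma data augmentation: conditional on
the PG latent variables every update of (beta, f_struc, f_unstruc) is a
joint draw from one Gaussian, the precisions have conjugate Gamma updates,
and the ICAR sum-to-zero constraint is imposed exactly by conditioning the
joint Gaussian draw on the component-sum functionals (kriging correction).

Priors default to the diffuse settings conventional in areal disease
mapping: beta ~ Normal(0, 31.6^2) (precision 0.001) and both precisions
~ Gamma(shape 1, rate 0.0005); all overridable through ModelSpec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular


from .geo import AdjacencyGraph
from .polya_gamma import rpg, seed_pg
from .synthetic import EDUCATION_LEVELS, WEALTH_QUINTILES, SurveyDataset
from .tabulate import BRACKETS, classify_age_group

DEFAULT_COVARIATES = ("urban", "education", "wealth_quintile")


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class SamplerSettings:
    n_iter: int = 20_000
    n_burnin: int = 5_000
    n_thin: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.n_thin < 1:
            raise ValueError("n_thin must be >= 1")


@dataclass
class ModelSpec:
    bracket: str = "lt20"
    covariates: Sequence[str] = DEFAULT_COVARIATES
    spatial: Literal["none", "besag", "bym"] = "bym"
    prior_beta_sd: float = 31.6227766  # precision 0.001
    tau_prior: tuple[float, float] = (1.0, 0.0005)  # Gamma(shape, rate)
    tau_fixed: tuple[float | None, float | None] | None = None  # pin precisions
    exclude_earlier_births: bool = False
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self) -> None:
        if self.bracket not in BRACKETS:
            raise ValueError(f"unknown bracket {self.bracket!r}")
        if self.spatial not in ("none", "besag", "bym"):
            raise ValueError(f"unknown spatial structure {self.spatial!r}")
        if self.tau_prior[0] <= 0 or self.tau_prior[1] <= 0:
            raise ValueError("tau prior shape and rate must be positive")


@dataclass
class DesignMatrix:
    y: np.ndarray  # binary response
    X: np.ndarray  # n x (1 + k) with leading intercept column
    columns: list[str]
    district_ids: np.ndarray  # per-row district id (object array of str)

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.district_ids):
            raise ValueError("design components have inconsistent lengths")
        rank = np.linalg.matrix_rank(self.X)
        if self.X.shape[0] >= self.X.shape[1] and rank < self.X.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {self.X.shape[1]} columns); "
                "check for collinear covariates"
            )


class SchemaError(ValueError):
    pass


def build_design(
    dataset: SurveyDataset,
    spec: ModelSpec,
    assignment: Mapping[str, str],
) -> DesignMatrix:
    """Dummy-coded design for one bracket model.

    Reference levels: rural residence, no education, lowest wealth quintile.
    y_i = 1 iff woman i's first birth falls inside ``spec.bracket`` (women
    with births outside the bracket, or none, count as 0 unless
    ``exclude_earlier_births`` drops women whose first birth preceded it).
    """
    df = dataset.records_frame()
    missing = sorted(set(df["cluster_id"]) - set(assignment))
    if missing:
        raise SchemaError(f"clusters without a district assignment: {missing}")
    bad_edu = sorted(set(df["education"]) - set(EDUCATION_LEVELS))
    if bad_edu:
        raise SchemaError(f"unknown education levels: {bad_edu}")
    bad_wq = sorted(set(df["wealth_quintile"]) - set(WEALTH_QUINTILES))
    if bad_wq:
        raise SchemaError(f"unknown wealth quintiles: {bad_wq}")

    brackets = np.array([classify_age_group(a) for a in df["age_first_birth"]], dtype=object)
    if spec.bracket == "lt20":
        y = np.array([b is not None for b in brackets], dtype=float)
    else:
        y = np.array([b == spec.bracket for b in brackets], dtype=float)

    keep = np.ones(len(df), dtype=bool)
    if spec.exclude_earlier_births and spec.bracket in ("16to17", "18to19"):
        lower = 16 if spec.bracket == "16to17" else 18
        afb = df["age_first_birth"].to_numpy(dtype=float)
        keep = ~(np.isfinite(afb) & (afb < lower))

    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for cov in spec.covariates:
        if cov == "urban":
            cols.append(df["urban"].to_numpy(dtype=float))
            names.append("urban")
        elif cov == "education":
            for lvl in EDUCATION_LEVELS[1:]:
                cols.append((df["education"] == lvl).to_numpy(dtype=float))
                names.append(f"education:{lvl}")
        elif cov == "wealth_quintile":
            for q in WEALTH_QUINTILES[1:]:
                cols.append((df["wealth_quintile"] == q).to_numpy(dtype=float))
                names.append(f"wealth:{q}")
        else:
            raise SchemaError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols)
    district = df["cluster_id"].map(dict(assignment)).to_numpy(dtype=object)
    return DesignMatrix(y=y[keep], X=X[keep], columns=names, district_ids=district[keep])


def icar_quadform(f: np.ndarray, adjacency: AdjacencyGraph, tau: float) -> float:
    """Log-density contribution of the Besag field (up to a constant):
    -(tau/2) * sum over neighbour pairs of (f_j - f_j')^2."""
    f = np.asarray(f, dtype=float)
    if f.shape[0] != len(adjacency.nodes):
        raise ValueError(f"effect vector length {f.shape[0]} != {len(adjacency.nodes)} districts")
    idx = {n: i for i, n in enumerate(adjacency.nodes)}
    s = 0.0
    for a, b in adjacency.edges:
        d = f[idx[a]] - f[idx[b]]
        s += d * d
    return -0.5 * tau * s


class Summary(NamedTuple):
    mean: float
    sd: float
    q025: float
    q975: float
    ci_width: float


@dataclass
class PosteriorFit:
    spec: ModelSpec
    beta: np.ndarray  # (S, k)
    beta_names: list[str]
    f_struc: np.ndarray  # (S, J) (zeros when absent)
    f_unstruc: np.ndarray  # (S, J)
    tau_struc: np.ndarray  # (S,)
    tau_unstruc: np.ndarray  # (S,)
    district_order: list[str]
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def f_spat(self) -> np.ndarray:
        return self.f_struc + self.f_unstruc

    def get(self, quantity: str) -> np.ndarray:
        """Draw vector for a named quantity, e.g. ``beta:urban``,
        ``f_struc:d007``, ``tau_unstruc``."""
        if quantity in ("tau_struc", "tau_unstruc"):
            return getattr(self, quantity)
        kind, _, name = quantity.partition(":")
        if kind == "beta":
            return self.beta[:, self.beta_names.index(name)]
        if kind in ("f_struc", "f_unstruc", "f_spat"):
            j = self.district_order.index(name)
            arr = self.f_spat() if kind == "f_spat" else getattr(self, kind)
            return arr[:, j]
        raise KeyError(f"unknown quantity {quantity!r}")


def posterior_summary(fit_or_draws, quantity: str | None = None) -> Summary:
    """Empirical mean, SD, equal-tailed 95% interval and its width."""
    draws = fit_or_draws.get(quantity) if isinstance(fit_or_draws, PosteriorFit) else np.asarray(fit_or_draws, float)
    if draws.size < 100:
        warnings.warn(f"only {draws.size} retained draws; summaries will be noisy", UserWarning)
    q025, q975 = np.quantile(draws, [0.025, 0.975])
    return Summary(float(draws.mean()), float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                   float(q025), float(q975), float(q975 - q025))


def _split_rhat(x: np.ndarray) -> float:
    # split the chain in halves and compare within/between variance
    s = (len(x) // 2) * 2
    halves = x[:s].reshape(2, -1)
    w = halves.var(axis=1, ddof=1).mean()
    b = halves.shape[1] * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (halves.shape[1] - 1) / halves.shape[1] * w + b / halves.shape[1]
    return float(np.sqrt(var_plus / w))


def log_likelihood(beta: np.ndarray, f: np.ndarray, design: DesignMatrix, dist_idx: np.ndarray) -> float:
    """Bernoulli log-likelihood at one parameter point (f = combined spatial
    effect per district)."""
    psi = design.X @ beta + f[dist_idx]
    # log p = y*psi - log(1 + exp(psi)), computed stably
    return float(np.sum(design.y * psi - np.logaddexp(0.0, psi)))


def fit_model(
    spec: ModelSpec,
    design: DesignMatrix,
    adjacency: AdjacencyGraph,
    temperature: float = 1.0,
) -> PosteriorFit:
    """Pólya-Gamma Gibbs sampler for the spatial logistic model.

    Reproducible given ``spec.sampler.seed`` (required).  The structured
    field satisfies its per-component sum-to-zero constraint in every
    retained draw; isolated districts are pinned at f_struc = 0.

    ``temperature`` tempers the likelihood to L^t (power posterior): the PG
    augmentation carries over with shape-t latent variables, and t = 0
    samples the prior.  Used by the marginal-likelihood estimator; ordinary
    fits leave it at 1.
    """
    if spec.sampler.seed is None:
        raise ValueError("a sampler seed is required for reproducibility")
    if not (0.0 <= temperature <= 1.0):
        raise ValueError("temperature must lie in [0, 1]")
    nodes = adjacency.nodes
    unknown = sorted(set(design.district_ids) - set(nodes))
    if unknown:
        raise ValueError(f"design references districts absent from adjacency: {unknown}")
    node_pos = {n: i for i, n in enumerate(nodes)}
    dist_idx = np.array([node_pos[d] for d in design.district_ids], dtype=np.int64)

    y, X = design.y, design.X
    n, k = X.shape
    J = len(nodes)
    kappa = temperature * (y - 0.5)

    rng = np.random.default_rng(spec.sampler.seed)
    seed_pg(int(rng.integers(2**31 - 1)))

    has_struc = spec.spatial in ("besag", "bym")
    has_unstruc = spec.spatial == "bym"
    dim = k + (J if has_struc else 0) + (J if has_unstruc else 0)
    u_off = k
    v_off = k + (J if has_struc else 0)

    Q = adjacency.laplacian()
    comps = adjacency.components()
    comp_idx = [np.array([node_pos[nd] for nd in c]) for c in comps]
    icar_rank = sum(len(c) - 1 for c in comps)
    # constraint matrix: one sum-to-zero row per component with >1 district,
    # plus pinning rows for isolated districts
    crows = []
    if has_struc:
        for ci in comp_idx:
            row = np.zeros(dim)
            row[u_off + ci] = 1.0
            crows.append(row)
    C = np.array(crows) if crows else None

    shape0, rate0 = spec.tau_prior
    tau_s = tau_v = 1.0
    if spec.tau_fixed is not None:
        if spec.tau_fixed[0] is not None:
            tau_s = float(spec.tau_fixed[0])
        if spec.tau_fixed[1] is not None:
            tau_v = float(spec.tau_fixed[1])

    beta = np.zeros(k)
    u = np.zeros(J)
    v = np.zeros(J)

    st = spec.sampler
    n_keep = (st.n_iter - st.n_burnin) // st.n_thin
    out_beta = np.empty((n_keep, k))
    out_u = np.zeros((n_keep, J))
    out_v = np.zeros((n_keep, J))
    out_ts = np.empty(n_keep)
    out_tv = np.empty(n_keep)

    prior_beta_prec = 1.0 / spec.prior_beta_sd**2
    kappa_X = X.T @ kappa  # constant across iterations
    kappa_Z = np.bincount(dist_idx, weights=kappa, minlength=J)

    kept = 0
    for it in range(st.n_iter):
        psi = X @ beta
        if has_struc:
            psi = psi + u[dist_idx]
        if has_unstruc:
            psi = psi + v[dist_idx]
        omega = rpg(psi, b=temperature) if temperature > 0 else np.zeros(n)

        # Gaussian block update of (beta, u, v) given omega
        P = np.zeros((dim, dim))
        r = np.zeros(dim)
        Xw = X * omega[:, None]
        P[:k, :k] = X.T @ Xw + prior_beta_prec * np.eye(k)
        r[:k] = kappa_X
        w_dist = np.bincount(dist_idx, weights=omega, minlength=J)
        if has_struc or has_unstruc:
            XtWZ = np.empty((k, J))
            for c in range(k):
                XtWZ[c] = np.bincount(dist_idx, weights=Xw[:, c], minlength=J)
        if has_struc:
            P[:k, u_off:u_off + J] = XtWZ
            P[u_off:u_off + J, :k] = XtWZ.T
            P[u_off:u_off + J, u_off:u_off + J] = tau_s * Q
            P[u_off + np.arange(J), u_off + np.arange(J)] += w_dist + 1e-10
            r[u_off:u_off + J] = kappa_Z
        if has_unstruc:
            P[:k, v_off:v_off + J] = XtWZ
            P[v_off:v_off + J, :k] = XtWZ.T
            P[v_off + np.arange(J), v_off + np.arange(J)] = w_dist + tau_v
            r[v_off:v_off + J] = kappa_Z
            if has_struc:
                P[u_off:u_off + J, v_off:v_off + J] = np.diag(w_dist)
                P[v_off:v_off + J, u_off:u_off + J] = np.diag(w_dist)

        chol = cho_factor(P, lower=True)
        mean = cho_solve(chol, r)
        z = rng.standard_normal(dim)
        theta = mean + solve_triangular(chol[0], z, lower=True, trans="T")
        if C is not None:
            # condition the joint Gaussian draw on C theta = 0 (exact)
            SigC = cho_solve(chol, C.T)  # dim x n_constraints
            M = C @ SigC
            theta = theta - SigC @ np.linalg.solve(M, C @ theta)

        beta = theta[:k]
        if has_struc:
            u = theta[u_off:u_off + J]
        if has_unstruc:
            v = theta[v_off:v_off + J]

        if spec.tau_fixed is None or spec.tau_fixed[0] is None:
            if has_struc:
                quad = float(u @ Q @ u)
                tau_s = rng.gamma(shape0 + 0.5 * icar_rank, 1.0 / (rate0 + 0.5 * quad))
        if spec.tau_fixed is None or spec.tau_fixed[1] is None:
            if has_unstruc:
                tau_v = rng.gamma(shape0 + 0.5 * J, 1.0 / (rate0 + 0.5 * float(v @ v)))

        if it >= st.n_burnin and (it - st.n_burnin) % st.n_thin == 0 and kept < n_keep:
            out_beta[kept] = beta
            if has_struc:
                out_u[kept] = u
            if has_unstruc:
                out_v[kept] = v
            out_ts[kept] = tau_s
            out_tv[kept] = tau_v
            kept += 1

    rhats = {name: _split_rhat(out_beta[:, c]) for c, name in enumerate(design.columns)}
    diagnostics = {"split_rhat_beta": rhats, "n_kept": kept}
    worst = max(rhats.values())
    if worst > 1.1:
        warnings.warn(
            f"possible non-convergence: max split-Rhat on beta = {worst:.3f} "
            f"({rhats})", ConvergenceWarning,
        )
    return PosteriorFit(
        spec=spec,
        beta=out_beta,
        beta_names=list(design.columns),
        f_struc=out_u,
        f_unstruc=out_v,
        tau_struc=out_ts,
        tau_unstruc=out_tv,
        district_order=list(nodes),
        diagnostics=diagnostics,
    )
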
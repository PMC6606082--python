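"""Model comparison by DIC and marginal log-likelihood.

DIC follows the classical construction: posterior mean deviance Dbar plus
the effective number of parameters p_D = Dbar - D(theta_bar), with
theta_bar the posterior mean of (beta, spatial effects).  Lower is better;
negative p_D is a known pathology of the plug-in form and is reported with
a warning rather than hidden.

The marginal log-likelihood (model evidence) is estimated by thermodynamic
integration over the power posterior p_t proportional to L^t * prior:

    log Z = integral over t in [0, 1] of E_t[log L] dt,

approximated by the trapezoid rule on a temperature ladder concentrated
near t = 0 (default t_i = (i/(L-1))^5), where the integrand changes
fastest under diffuse priors.  Absolute values are estimator-dependent;
only differences between models fitted to the same data are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bym import DesignMatrix, ModelSpec, PosteriorFit, fit_model
from .geo import AdjacencyGraph


@dataclass
class FitDiagnostics:
    label: str
    dic: float
    p_d: float
    dbar: float
    mll: float | None = None
    mll_se: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.p_d):
            raise ValueError("effective number of parameters is not finite")
        assert abs(self.dic - (self.dbar + self.p_d)) < 1e-8, "DIC identity violated"


def _pointwise_loglik(fit: PosteriorFit, design: DesignMatrix, chunk: int = 512) -> np.ndarray:
    node_pos = {n: i for i, n in enumerate(fit.district_order)}
    dist_idx = np.array([node_pos[d] for d in design.district_ids])
    f = fit.f_spat()
    out = np.empty(fit.n_draws)
    for s0 in range(0, fit.n_draws, chunk):
        s1 = min(s0 + chunk, fit.n_draws)
        psi = design.X @ fit.beta[s0:s1].T + f[s0:s1, :].T[dist_idx, :]
        ll = design.y[:, None] * psi - np.logaddexp(0.0, psi)
        out[s0:s1] = ll.sum(axis=0)
    return out


def compute_dic(fit: PosteriorFit, design: DesignMatrix, label: str = "") -> FitDiagnostics:
    """Deviance information criterion from posterior draws.

    D(theta) = -2 log L(theta); Dbar averages over draws; the plug-in
    deviance evaluates at the posterior mean of (beta, f_struc + f_unstruc).
    """
    ll = _pointwise_loglik(fit, design)
    bad = np.flatnonzero(~np.isfinite(ll))
    if bad.size:
        raise FloatingPointError(f"non-finite likelihood at draw(s) {bad[:5].tolist()}")
    dbar = float(-2.0 * ll.mean())
    node_pos = {n: i for i, n in enumerate(fit.district_order)}
    dist_idx = np.array([node_pos[d] for d in design.district_ids])
    beta_bar = fit.beta.mean(axis=0)
    f_bar = fit.f_spat().mean(axis=0)
    psi = design.X @ beta_bar + f_bar[dist_idx]
    d_hat = float(-2.0 * np.sum(design.y * psi - np.logaddexp(0.0, psi)))
    p_d = dbar - d_hat
    if p_d < 0:
        warnings.warn(
            f"negative effective number of parameters (p_D = {p_d:.2f}); "
            "the plug-in DIC is unreliable for this fit", UserWarning,
        )
    return FitDiagnostics(label=label, dic=dbar + p_d, p_d=p_d, dbar=dbar)


def default_ladder(n: int = 21, power: float = 5.0) -> np.ndarray:
    """Temperature schedule t_i = (i/(n-1))^power on [0, 1]."""
    return (np.arange(n) / (n - 1)) ** power


def _check_ladder(ladder: np.ndarray) -> np.ndarray:
    ladder = np.asarray(ladder, dtype=float)
    if ladder[0] != 0.0 or ladder[-1] != 1.0:
        raise ValueError("temperature ladder must run from 0 to 1")
    if np.any(np.diff(ladder) <= 0):
        raise ValueError("temperature ladder must be strictly increasing")
    return ladder


def _trapezoid_mll(ts: np.ndarray, means: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    dt = np.diff(ts)
    w = np.zeros_like(ts)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    mll = float(np.sum(w * means))
    se = float(np.sqrt(np.sum((w * ses) ** 2)))
    return mll, se


def _batch_se(x: np.ndarray, n_batches: int = 20) -> float:
    # batch-means standard error of the chain mean (accounts for autocorrelation)
    m = len(x) // n_batches
    if m < 2:
        return float(x.std(ddof=1) / np.sqrt(max(len(x), 2)))
    b = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(b.std(ddof=1) / np.sqrt(n_batches))


def compute_mll(
    spec: ModelSpec,
    design: DesignMatrix,
    adjacency: AdjacencyGraph,
    ladder: Sequence[float] | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Thermodynamic-integration estimate of the marginal log-likelihood.

    Runs the tempered Pólya-Gamma Gibbs chain at each ladder temperature,
    averages the (untempered) log-likelihood, and integrates by trapezoid.
    Returns (mll, Monte-Carlo standard error).
    """
    ts = _check_ladder(default_ladder() if ladder is None else np.asarray(ladder))
    seed = spec.sampler.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required")
    means = np.empty(len(ts))
    ses = np.empty(len(ts))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tempered chains trip Rhat heuristics by design
        for i, t in enumerate(ts):
            spec_t = replace(spec, sampler=replace(spec.sampler, seed=seed + 1000 * i))
            fit_t = fit_model(spec_t, design, adjacency, temperature=float(t))
            ll = _pointwise_loglik(fit_t, design)
            means[i] = ll.mean()
            ses[i] = _batch_se(ll)
    return _trapezoid_mll(ts, means, ses)


def thermodynamic_mll_generic(
    log_lik: Callable[[np.ndarray], float],
    log_prior: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    ladder: Sequence[float],
    n_iter: int = 4000,
    n_burnin: int = 1000,
    seed: int = 0,
    step0: float = 1.0,
) -> tuple[float, float]:
    """Power-posterior evidence estimate for an arbitrary small model.

    Adaptive random-walk Metropolis per temperature (warm-started along the
    ladder), trapezoid integration of E_t[log L].  Intended for low
    dimensional models and as an independent route to the same estimator
    the spatial models use through :func:`compute_mll`.
    """
    ts = _check_ladder(np.asarray(ladder, dtype=float))
    rng = np.random.default_rng(seed)
    theta = np.atleast_1d(np.asarray(theta0, dtype=float)).copy()
    d = theta.size
    step = step0
    means, ses = np.empty(len(ts)), np.empty(len(ts))
    target_acc = 0.44 if d == 1 else 0.28
    for i, t in enumerate(ts):
        lp = log_prior(theta) + t * log_lik(theta)
        lls = np.empty(n_iter - n_burnin)
        n_acc = 0
        for it in range(n_iter):
            prop = theta + step * rng.standard_normal(d)
            lp_prop = log_prior(prop) + t * log_lik(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                n_acc += 1
            if it < n_burnin and (it + 1) % 100 == 0:
                acc = n_acc / (it + 1)
                step *= np.exp(0.5 * (acc - target_acc))
            if it >= n_burnin:
                lls[it - n_burnin] = log_lik(theta)
        means[i] = lls.mean()
        ses[i] = _batch_se(lls)
    return _trapezoid_mll(ts, means, ses)


def compare_models(diagnostics: Sequence[FitDiagnostics], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Comparison table with best-by-DIC / best-by-MLL flags (ties share)."""
    if len(diagnostics) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    for i, d in enumerate(diagnostics):
        rows.append(
            {
                "model": labels[i] if labels else d.label,
                "dic": d.dic,
                "p_d": d.p_d,
                "dbar": d.dbar,
                "mll": d.mll,
                "mll_se": d.mll_se,
            }
        )
    df = pd.DataFrame(rows)
    best_dic = df["dic"].min()
    df["best_by_dic"] = np.isclose(df["dic"], best_dic)
    if df["mll"].notna().all():
        best_mll = df["mll"].max()
        df["best_by_mll"] = np.isclose(df["mll"], best_mll)
    else:
        df["best_by_mll"] = pd.NA
    if df["best_by_dic"].sum() > 1:
        df.attrs["dic_tie"] = True
    return df
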
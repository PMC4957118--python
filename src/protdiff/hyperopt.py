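"""Per-protein standardization, the dataset-level marginal-likelihood
objective and empirical-Bayes fitting of the shared hyperparameters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import IntensityMatrix
from .model_core import (
    HyperParams,
    log_ml_h0_from_stats,
    log_ml_h1_from_stats,
    posterior_h1,
    prior_h1,
)

__all__ = [
    "FitResult",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
    "standardize",
    "total_log_marginal",
    "fit_hyperparameters",
    "posterior_table",
]

# box bounds for (mu0, alpha, beta, kappa, phi); data is standardized to unit
# scale before fitting so diffuse-but-proper boxes suffice
DEFAULT_BOUNDS = {
    "mu0": (-5.0, 5.0),
    "alpha": (0.5, 50.0),
    "beta": (0.01, 50.0),
    "kappa": (0.01, 100.0),
    "phi": (0.01, 100.0),
}

DEFAULT_INIT = HyperParams(mu0=0.0, alpha=2.0, beta=1.0, tau0=0.0, kappa=1.0, phi=1.0)


@dataclass(frozen=True)
class FitResult:
    hyperparams: HyperParams
    objective_value: float
    converged: bool
    n_iterations: int


def standardize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Standardize each protein's observed values to mean 0, sd 1 (ddof=1).

    Observed values are pooled across both groups so that between-group
    differences survive as signal. Proteins with fewer than two observed
    values are left untouched; zero-variance proteins are centred only. Both
    cases are recorded in ``flags`` and warned about.
    """
    out = matrix.copy()
    obs = ~out.mask
    n_obs = obs.sum(axis=1)
    skipped, centred_only = [], []
    for i in range(out.n_proteins):
        if n_obs[i] < 2:
            skipped.append(str(out.protein_ids[i]))
            continue
        vals = out.values[i, obs[i]]
        sd = vals.std(ddof=1)
        if sd == 0.0:
            out.values[i, obs[i]] = vals - vals.mean()
            centred_only.append(str(out.protein_ids[i]))
        else:
            out.values[i, obs[i]] = (vals - vals.mean()) / sd
    if skipped:
        warnings.warn(f"{len(skipped)} protein(s) with <2 observed values left unstandardized")
        out.flags["unstandardized"] = skipped
    if centred_only:
        warnings.warn(f"{len(centred_only)} zero-variance protein(s) centred only")
        out.flags["centred_only"] = centred_only
    return out


def _sufficient_stats(matrix: IntensityMatrix):
    """Per-protein raw sums needed to evaluate the objective at any mu0."""
    obs = ~matrix.mask
    vals = np.where(obs, matrix.values, 0.0)
    c, t = matrix.ctrl_cols, matrix.trt_cols
    n1 = obs[:, c].sum(axis=1).astype(float)
    n2 = obs[:, t].sum(axis=1).astype(float)
    sum1 = vals[:, c].sum(axis=1)
    sum2 = vals[:, t].sum(axis=1)
    sq = (vals[:, c] ** 2).sum(axis=1) + (vals[:, t] ** 2).sum(axis=1)
    f1 = (len(c) - n1) / len(c)
    f2 = (len(t) - n2) / len(t)
    return n1, n2, sum1, sum2, sq, f1, f2


def _log_mls(stats, hp: HyperParams):
    """Vectorized (log_ml_h0, log_ml_h1) for every protein."""
    n1, n2, sum1, sum2, sq, _, _ = stats
    n = n1 + n2
    # residual sums under mu0 (H0) and (mu0, tau0) (H1)
    s0 = (sum1 + sum2) - n * hp.mu0
    ss0 = sq - 2.0 * hp.mu0 * (sum1 + sum2) + n * hp.mu0**2
    s2_1 = sum2 - n2 * (hp.mu0 + hp.tau0)
    s_1 = (sum1 - n1 * hp.mu0) + s2_1
    ss1 = (
        sq
        - 2.0 * hp.mu0 * sum1
        + n1 * hp.mu0**2
        - 2.0 * (hp.mu0 + hp.tau0) * sum2
        + n2 * (hp.mu0 + hp.tau0) ** 2
    )
    l0 = log_ml_h0_from_stats(n, s0, ss0, hp.alpha, hp.beta)
    l1 = log_ml_h1_from_stats(n1, n2, s_1, s2_1, ss1, hp.alpha, hp.beta, hp.kappa)
    return l0, l1


def _objective_from_stats(stats, hp: HyperParams, form: str) -> float:
    l0, l1 = _log_mls(stats, hp)
    _, _, _, _, _, f1, f2 = stats
    p = prior_h1(f1, f2, hp.phi, form)
    with np.errstate(divide="ignore"):
        terms = np.logaddexp(np.log(p) + l1, np.log1p(-p) + l0)
    return float(terms.sum())


def total_log_marginal(matrix: IntensityMatrix, hp: HyperParams, form: str = "polynomial") -> float:
    """Dataset-level objective: sum over proteins of the log two-component
    mixture ``log(p_H1 * ML_H1 + (1 - p_H1) * ML_H0)``."""
    return _objective_from_stats(_sufficient_stats(matrix), hp, form)


def fit_hyperparameters(
    matrix: IntensityMatrix,
    form: str = "polynomial",
    init: HyperParams | None = None,
    bounds: dict | None = None,
) -> FitResult:
    """Maximize ``total_log_marginal`` over (mu0, alpha, beta, kappa, phi)
    with ``tau0`` pinned to 0, using bounded L-BFGS-B.

    Deterministic given the data and the initial point. Non-convergence is
    reported via ``converged=False`` with the best point found, never raised.
    """
    init = init or DEFAULT_INIT
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    stats = _sufficient_stats(matrix)
    names = ("mu0", "alpha", "beta", "kappa", "phi")
    x0 = np.array([getattr(init, k) for k in names])
    box = [b[k] for k in names]
    x0 = np.clip(x0, [lo for lo, _ in box], [hi for _, hi in box])

    def neg(x):
        hp = HyperParams(mu0=x[0], alpha=x[1], beta=x[2], tau0=0.0, kappa=x[3], phi=x[4])
        val = _objective_from_stats(stats, hp, form)
        if not np.isfinite(val):
            return 1e12
        return -val

    res = minimize(neg, x0, method="L-BFGS-B", bounds=box)
    f0 = -neg(x0)
    best_x, best_f = (res.x, -res.fun) if -res.fun >= f0 else (x0, f0)
    hp = HyperParams(
        mu0=float(best_x[0]),
        alpha=float(best_x[1]),
        beta=float(best_x[2]),
        tau0=0.0,
        kappa=float(best_x[3]),
        phi=float(best_x[4]),
    )
    if not res.success:
        warnings.warn(f"hyperparameter optimizer did not converge: {res.message}")
    return FitResult(hp, float(best_f), bool(res.success), int(res.nit))


def posterior_table(
    matrix: IntensityMatrix, hp: HyperParams, form: str = "polynomial"
) -> pd.DataFrame:
    """Per-protein prior, log marginals and posterior for a (typically
    standardized) matrix at given hyperparameters."""
    stats = _sufficient_stats(matrix)
    n1, n2, _, _, _, f1, f2 = stats
    l0, l1 = _log_mls(stats, hp)
    p = prior_h1(f1, f2, hp.phi, form)
    post = posterior_h1(p, l1, l0)
    nc, nt = len(matrix.ctrl_cols), len(matrix.trt_cols)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "n_obs_ctrl": n1.astype(int),
            "n_obs_trt": n2.astype(int),
            "n_missing_ctrl": (nc - n1).astype(int),
            "n_missing_trt": (nt - n2).astype(int),
            "f_ctrl": f1,
            "f_trt": f2,
            "prior_h1": np.broadcast_to(p, l0.shape),
            "log_ml_h0": l0,
            "log_ml_h1": l1,
            "posterior_h1": np.broadcast_to(post, l0.shape),
        }
    )
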
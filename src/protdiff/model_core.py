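"""Priors from missing-value frequencies, conjugate marginal likelihoods and
the Bayes-rule posterior.

Model
-----
Observed log-intensities of one protein are Normal. Under the null (H0) both
groups share mean ``mu`` and variance ``sigma^2``; under the alternative (H1)
the treatment group mean is shifted by ``tau``. Conjugate priors::

    mu      ~ N(mu0, sigma^2)
    tau     ~ N(tau0, kappa * sigma^2)
    sigma^2 ~ InverseGamma(alpha, beta)

Integrating the parameters out in closed form gives a multivariate-t type
marginal density. With residuals ``r`` (control: ``y - mu0``, treatment:
``z - mu0 - tau0``), total count ``n = n_ctrl + n_trt``, sums
``s = sum(r)``, ``s2 = sum(r_trt)`` and ``ss = sum(r^2)``, the covariance of
the data given ``sigma^2`` is ``sigma^2 * (I + 1 1' + kappa e_T e_T')`` and
the Woodbury identity yields the quadratic form and determinant used below;
the ``sigma^2`` integral then produces the ``Gamma``/``log`` terms.

The prior probability of H1 is driven purely by the difference in per-group
missing-value frequencies, in one of two forms (``phi > 0``):

    polynomial:   p = (1 + |df|^phi) / 2
    exponential:  p = 1 - exp(-|df| / phi) / 2

Both are 0.5 at equal frequencies, tend to 1 as ``phi -> 0`` (for ``|df|>0``)
and to 0.5 as ``phi -> inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GroupObservations",
    "HyperParams",
    "ProteinPosterior",
    "PRIOR_FORMS",
    "missing_frequencies",
    "prior_h1",
    "log_marginal_likelihood_h0",
    "log_marginal_likelihood_h1",
    "log_ml_h0_from_stats",
    "log_ml_h1_from_stats",
    "posterior_h1",
]

PRIOR_FORMS = ("polynomial", "exponential")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GroupObservations:
    """Observed intensities and missing-value counts of one protein."""

    values_ctrl: tuple = ()
    values_trt: tuple = ()
    n_missing_ctrl: int = 0
    n_missing_trt: int = 0

    def __post_init__(self):
        object.__setattr__(self, "values_ctrl", tuple(float(v) for v in self.values_ctrl))
        object.__setattr__(self, "values_trt", tuple(float(v) for v in self.values_trt))
        if self.n_missing_ctrl < 0 or self.n_missing_trt < 0:
            raise ValueError("missing counts must be non-negative")
        for v in self.values_ctrl + self.values_trt:
            if not math.isfinite(v):
                raise ValueError("observed intensities must be finite")

    @property
    def n_ctrl(self) -> int:
        return len(self.values_ctrl)

    @property
    def n_trt(self) -> int:
        return len(self.values_trt)


@dataclass(frozen=True)
class HyperParams:
    """The six model hyperparameters.

    ``tau0`` is pinned to 0 by the fitting pipeline (treatment effects are
    equally likely to be positive or negative); it is kept as a field so the
    likelihood functions stay general.
    """

    mu0: float = 0.0
    alpha: float = 2.0
    beta: float = 1.0
    tau0: float = 0.0
    kappa: float = 1.0
    phi: float = 1.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if not self.phi > 0:
            raise ValueError("phi must be positive")


@dataclass(frozen=True)
class ProteinPosterior:
    """Per-protein prior, log marginal likelihoods and posterior."""

    prior_h1: float
    log_ml_h0: float
    log_ml_h1: float
    posterior_h1: float


def missing_frequencies(obs: GroupObservations) -> tuple[float, float]:
    """Per-group missing-value frequencies ``missing / (missing + observed)``.

    Raises ``ValueError`` if either group has zero total samples.
    """
    tot_ctrl = obs.n_ctrl + obs.n_missing_ctrl
    tot_trt = obs.n_trt + obs.n_missing_trt
    if tot_ctrl == 0 or tot_trt == 0:
        raise ValueError("each group needs at least one sample (observed or missing)")
    return obs.n_missing_ctrl / tot_ctrl, obs.n_missing_trt / tot_trt


def prior_h1(f_ctrl, f_trt, phi: float, form: str = "polynomial"):
    """Prior probability of differential expression from missing frequencies.

    Symmetric in the two frequencies, equals exactly 0.5 when they agree and
    increases towards 1 with the absolute frequency difference. ``phi``
    controls the sensitivity: small ``phi`` pushes the prior towards 1, large
    ``phi`` towards 0.5. Accepts scalars or arrays.
    """
    if form not in PRIOR_FORMS:
        raise ValueError(f"form must be one of {PRIOR_FORMS}")
    if not phi > 0:
        raise ValueError("phi must be positive")
    f_ctrl = np.asarray(f_ctrl, dtype=float)
    f_trt = np.asarray(f_trt, dtype=float)
    if np.any(f_ctrl < 0) or np.any(f_ctrl > 1) or np.any(f_trt < 0) or np.any(f_trt > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    df = np.abs(f_ctrl - f_trt)
    if form == "polynomial":
        # guard df == 0 explicitly: 0**phi is fine for phi > 0 but keep the
        # equal-frequency case exact
        p = np.where(df > 0, 0.5 * (1.0 + df ** phi), 0.5)
    else:
        p = np.where(df > 0, 1.0 - 0.5 * np.exp(-df / phi), 0.5)
    if p.ndim == 0:
        return float(p)
    return p


def log_ml_h0_from_stats(n, s, ss, alpha, beta):
    """Vectorized H0 log marginal likelihood from residual statistics.

    ``n``: observed count, ``s``: sum of residuals ``d - mu0`` pooled over
    both groups, ``ss``: sum of squared residuals. Returns 0 where ``n == 0``
    (empty-product convention).
    """
    n = np.asarray(n, dtype=float)
    q = ss - s * s / (1.0 + n)
    return (
        gammaln(alpha + n / 2.0)
        - gammaln(alpha)
        + alpha * np.log(beta)
        - (alpha + n / 2.0) * np.log(beta + q / 2.0)
        - (n / 2.0) * _LOG_2PI
        - 0.5 * np.log1p(n)
    )


def log_ml_h1_from_stats(n_ctrl, n_trt, s, s2, ss, alpha, beta, kappa):
    """Vectorized H1 log marginal likelihood from residual statistics.

    ``s`` sums residuals over both groups (treatment residuals are
    ``z - mu0 - tau0``), ``s2`` sums the treatment residuals only, ``ss`` is
    the total sum of squares. Reduces to the H0 expression as ``kappa -> 0``
    and to a single-group marginal when one group is empty.
    """
    n_ctrl = np.asarray(n_ctrl, dtype=float)
    n_trt = np.asarray(n_trt, dtype=float)
    n = n_ctrl + n_trt
    det = (1.0 + n) * (1.0 + kappa * n_trt) - kappa * n_trt**2
    num = (
        (1.0 + kappa * n_trt) * s * s
        - 2.0 * kappa * n_trt * s * s2
        + kappa * (1.0 + n) * s2 * s2
    )
    q = ss - num / det
    return (
        gammaln(alpha + n / 2.0)
        - gammaln(alpha)
        + alpha * np.log(beta)
        - (alpha + n / 2.0) * np.log(beta + q / 2.0)
        - (n / 2.0) * _LOG_2PI
        - 0.5 * np.log(det)
    )


def _residual_stats(obs: GroupObservations, hp: HyperParams):
    y = np.asarray(obs.values_ctrl, dtype=float) - hp.mu0
    z = np.asarray(obs.values_trt, dtype=float) - hp.mu0 - hp.tau0
    s2 = float(z.sum())
    s = float(y.sum()) + s2
    ss = float((y * y).sum() + (z * z).sum())
    return s, s2, ss


def log_marginal_likelihood_h0(obs: GroupObservations, hp: HyperParams) -> float:
    """Log marginal density of the pooled observed values under H0.

    ``mu`` and ``sigma^2`` are integrated out; the treatment residuals use
    ``mu0`` only (no shift under the null). Returns 0.0 when no value is
    observed in either group.
    """
    y = np.asarray(obs.values_ctrl, dtype=float) - hp.mu0
    z = np.asarray(obs.values_trt, dtype=float) - hp.mu0
    n = obs.n_ctrl + obs.n_trt
    s = float(y.sum() + z.sum())
    ss = float((y * y).sum() + (z * z).sum())
    return float(log_ml_h0_from_stats(n, s, ss, hp.alpha, hp.beta))


def log_marginal_likelihood_h1(obs: GroupObservations, hp: HyperParams) -> float:
    """Log marginal density under H1 with ``mu``, ``tau``, ``sigma^2``
    integrated out."""
    s, s2, ss = _residual_stats(obs, hp)
    return float(
        log_ml_h1_from_stats(obs.n_ctrl, obs.n_trt, s, s2, ss, hp.alpha, hp.beta, hp.kappa)
    )


def posterior_h1(prior, log_ml_h1, log_ml_h0):
    """Bayes-rule posterior probability of H1, computed via log-sum-exp.

    Accepts scalars or arrays. Degenerate priors 0 and 1 short-circuit.
    """
    prior = np.asarray(prior, dtype=float)
    log_ml_h1 = np.asarray(log_ml_h1, dtype=float)
    log_ml_h0 = np.asarray(log_ml_h0, dtype=float)
    if np.any(prior < 0) or np.any(prior > 1):
        raise ValueError("prior must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_num = np.log(prior) + log_ml_h1
        log_alt = np.log1p(-prior) + log_ml_h0
    post = np.exp(log_num - np.logaddexp(log_num, log_alt))
    post = np.where(prior == 1.0, 1.0, np.where(prior == 0.0, 0.0, post))
    if post.ndim == 0:
        return float(post)
    return post


def protein_posterior(
    obs: GroupObservations, hp: HyperParams, form: str = "polynomial"
) -> ProteinPosterior:
    """Full per-protein computation: prior, both marginals, posterior."""
    f_ctrl, f_trt = missing_frequencies(obs)
    p = prior_h1(f_ctrl, f_trt, hp.phi, form)
    l0 = log_marginal_likelihood_h0(obs, hp)
    l1 = log_marginal_likelihood_h1(obs, hp)
    return ProteinPosterior(p, l0, l1, posterior_h1(p, l1, l0))
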
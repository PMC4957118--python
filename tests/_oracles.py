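"""Independent numerical oracles used by the test suite.

Marginal likelihoods are recomputed by direct numerical integration of the
generative densities (no conjugate algebra shared with the implementation):
an adaptive outer integral over sigma^2 and tensor Gauss-Legendre panels over
the location parameters with data-driven bounds.
"""

import numpy as np
from scipy import integrate, stats


def _gl_nodes(lo, hi, order):
    x, w = np.polynomial.legendre.leggauss(order)
    return 0.5 * (hi - lo) * x + 0.5 * (hi + lo), 0.5 * (hi - lo) * w


def quad_log_ml_h0(values, hp, order=200):
    """2-D quadrature of N(y; mu, s2) * N(mu; mu0, s2) * IG(s2; alpha, beta)."""
    d = np.asarray(values, dtype=float)
    if d.size == 0:
        return 0.0

    def outer(s2):
        sd = np.sqrt(s2)
        pad = 10.0 * sd + 2.0
        lo = min(hp.mu0, d.min()) - pad
        hi = max(hp.mu0, d.max()) + pad
        mu, w = _gl_nodes(lo, hi, order)
        logf = (
            stats.norm.logpdf(d[:, None], mu[None, :], sd).sum(axis=0)
            + stats.norm.logpdf(mu, hp.mu0, sd)
        )
        return float(np.sum(w * np.exp(logf))) * stats.invgamma.pdf(s2, hp.alpha, scale=hp.beta)

    val, _ = integrate.quad(outer, 0.0, np.inf, limit=300)
    return float(np.log(val))


def quad_log_ml_h1(values_ctrl, values_trt, hp, order=260):
    """3-D quadrature with mu, tau and sigma^2 all integrated numerically."""
    y = np.asarray(values_ctrl, dtype=float)
    z = np.asarray(values_trt, dtype=float)
    if y.size == 0 and z.size == 0:
        return 0.0
    d = np.concatenate([y, z])

    def outer(s2):
        sd = np.sqrt(s2)
        sd_tau = np.sqrt(hp.kappa * s2)
        pad = 10.0 * sd + 2.0
        mu_lo = min(hp.mu0, d.min()) - pad
        mu_hi = max(hp.mu0, d.max()) + pad
        spread = (d.max() - d.min()) if d.size else 0.0
        tpad = 10.0 * sd_tau + 10.0 * sd + spread + 2.0
        mu, wm = _gl_nodes(mu_lo, mu_hi, order)
        tau, wt = _gl_nodes(hp.tau0 - tpad, hp.tau0 + tpad, order)
        logf = np.zeros((order, order))
        if y.size:
            logf += stats.norm.logpdf(y[:, None], mu[None, :], sd).sum(axis=0)[:, None]
        if z.size:
            mt = mu[:, None] + tau[None, :]
            logf += stats.norm.logpdf(z[:, None, None], mt[None, :, :], sd).sum(axis=0)
        logf += stats.norm.logpdf(mu, hp.mu0, sd)[:, None]
        logf += stats.norm.logpdf(tau, hp.tau0, sd_tau)[None, :]
        inner = float(np.einsum("i,j,ij->", wm, wt, np.exp(logf)))
        return inner * stats.invgamma.pdf(s2, hp.alpha, scale=hp.beta)

    val, _ = integrate.quad(outer, 0.0, np.inf, limit=300)
    return float(np.log(val))


def brute_expected_fdr(posteriors, p_th, c):
    """Literal sum-based expected FDR."""
    num = 0.0
    k = 0
    for p in posteriors:
        if p >= p_th:
            num += 1.0 - p
            k += 1
    if k == 0 and c == 0:
        return float("nan")
    return num / (c + k)


def brute_select_threshold(posteriors, alpha, c):
    """Enumerate every unique posterior as a candidate threshold."""
    best = None
    for th in sorted(set(posteriors)):
        e = brute_expected_fdr(posteriors, th, c)
        if not np.isnan(e) and e <= alpha:
            best = th
            break
    return best


def trapezoid_auroc(scores, labels):
    """ROC curve built threshold-by-threshold, integrated by trapezoids."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [np.mean(scores[labels] >= t) for t in thresholds]
    fpr = [np.mean(scores[~labels] >= t) for t in thresholds]
    return float(np.trapezoid(tpr, fpr))
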
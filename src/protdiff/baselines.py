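"""Comparator methods: classical two-sample tests with optional missing-value
imputation."""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.impute import KNNImputer

from .data import IntensityMatrix

__all__ = ["TESTS", "IMPUTATIONS", "MethodSpec", "impute", "test_per_protein"]

TESTS = ("t", "wilcoxon_rank_sum", "kruskal_wallis", "kolmogorov_smirnov", "permutation")
IMPUTATIONS = ("none", "knn", "pca_kdr", "pca_tsr")


@dataclass(frozen=True)
class MethodSpec:
    """A comparator: one two-sample test, optionally preceded by imputation."""

    test: str
    imputation: str = "none"
    test_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.test not in TESTS:
            raise ValueError(f"test must be one of {TESTS}")
        if self.imputation not in IMPUTATIONS:
            raise ValueError(f"imputation must be one of {IMPUTATIONS}")
        if self.test == "permutation" and self.test_params.get("n_permutations", 1000) < 100:
            raise ValueError("permutation count must be >= 100")
        if self.imputation == "knn" and self.test_params.get("k", 10) < 1:
            raise ValueError("k must be >= 1 for KNN")

    @property
    def name(self) -> str:
        return self.test if self.imputation == "none" else f"{self.test}+{self.imputation}"


def _knn_impute(data: np.ndarray, k: int) -> np.ndarray:
    # proteins are rows; KNNImputer imputes each column from the k nearest
    # rows under nan-aware Euclidean distance
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = KNNImputer(n_neighbors=k, weights="uniform").fit_transform(data)
    if out.shape != data.shape:  # all-NaN columns get dropped by sklearn
        out = data.copy()
        filled = KNNImputer(n_neighbors=k, weights="uniform", keep_empty_features=True)
        out = filled.fit_transform(data)
    return out


def _pca_impute(data: np.ndarray, n_components: int, scheme: str, max_iter: int, tol: float):
    """Iterative PCA model-based imputation (known-data / trimmed-scores
    regression flavours).

    Fits a rank-q model to the current completed matrix and re-estimates the
    missing part of each row from its observed part, iterating to
    convergence. KDR solves the least-squares score from the loadings
    restricted to observed variables; TSR regresses through the rank-q
    covariance (ridge-stabilized).
    """
    miss = np.isnan(data)
    x = data.copy()
    col_mean = np.nanmean(np.where(miss, np.nan, data), axis=0)
    col_mean = np.where(np.isnan(col_mean), np.nanmean(data), col_mean)
    x[miss] = np.take(col_mean, np.nonzero(miss)[1])
    q = min(n_components, min(x.shape) - 1)
    q = max(q, 1)
    converged = False
    for _ in range(max_iter):
        mean = x.mean(axis=0)
        xc = x - mean
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        loadings = vt[:q].T  # variables x components
        prev = x[miss].copy()
        if scheme == "kdr":
            for i in np.flatnonzero(miss.any(axis=1)):
                o, m = ~miss[i], miss[i]
                lo = loadings[o]
                t, *_ = np.linalg.lstsq(lo, xc[i, o], rcond=None)
                x[i, m] = mean[m] + loadings[m] @ t
        else:  # tsr: conditional mean through the rank-q covariance
            lam = (s[:q] ** 2) / max(x.shape[0] - 1, 1)
            cov_q = (loadings * lam) @ loadings.T
            ridge = 1e-8 * np.trace(cov_q) / cov_q.shape[0] + 1e-12
            for i in np.flatnonzero(miss.any(axis=1)):
                o, m = ~miss[i], miss[i]
                coo = cov_q[np.ix_(o, o)] + ridge * np.eye(int(o.sum()))
                x[i, m] = mean[m] + cov_q[np.ix_(m, o)] @ np.linalg.solve(coo, xc[i, o])
        delta = np.max(np.abs(x[miss] - prev)) if miss.any() else 0.0
        if delta < tol:
            converged = True
            break
    if not converged and miss.any():
        warnings.warn("iterative PCA imputation did not converge; returning last iterate")
    return x


def impute(matrix: IntensityMatrix, method: str, **params) -> IntensityMatrix:
    """Return a complete matrix; observed entries are never altered.

    Parameters: ``k`` (KNN neighbours, default 10), ``n_components`` (PCA
    rank, default 2), ``max_iter`` / ``tol`` for the iterative schemes.
    Proteins with every entry missing fall back to the global observed mean
    (flagged).
    """
    if method not in IMPUTATIONS:
        raise ValueError(f"method must be one of {IMPUTATIONS}")
    out = matrix.copy()
    if method == "none" or not out.mask.any():
        return out
    data = out.observed()  # NaN-masked copy

    all_missing = np.flatnonzero(np.isnan(data).all(axis=1))
    if all_missing.size:
        warnings.warn(f"{all_missing.size} protein(s) fully missing; using global mean")
        out.flags["fully_missing"] = [str(out.protein_ids[i]) for i in all_missing]
        data[all_missing] = np.nanmean(data)

    if method == "knn":
        filled = _knn_impute(data, int(params.get("k", 10)))
    else:
        filled = _pca_impute(
            data,
            int(params.get("n_components", 2)),
            "kdr" if method == "pca_kdr" else "tsr",
            int(params.get("max_iter", 100)),
            float(params.get("tol", 1e-6)),
        )
    # restore observed entries bitwise
    filled[~matrix.mask] = matrix.values[~matrix.mask]
    for i in all_missing:
        filled[i] = np.nanmean(matrix.values[~matrix.mask])
    out.values = filled
    out.mask = np.zeros_like(out.mask)
    return out


def _permutation_pvalues(ctrl: np.ndarray, trt: np.ndarray, n_permutations: int, seed: int):
    """Two-sided permutation test on the difference of group means.

    Exhaustive when the number of distinct label assignments is <= 10^4,
    otherwise ``n_permutations`` seeded draws with the add-one convention
    (p in [1/(B+1), 1]).
    """
    n1, n2 = ctrl.shape[1], trt.shape[1]
    data = np.concatenate([ctrl, trt], axis=1)
    obs = np.abs(trt.mean(axis=1) - ctrl.mean(axis=1))
    n = n1 + n2
    n_exhaustive = math.comb(n, n1)
    if n_exhaustive <= 10_000:
        count = np.zeros(data.shape[0])
        total = 0
        csum = data.sum(axis=1)
        for combo in itertools.combinations(range(n), n1):
            c = data[:, combo].sum(axis=1)
            stat = np.abs((csum - c) / n2 - c / n1)
            count += stat >= obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = np.zeros(data.shape[0])
    csum = data.sum(axis=1)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        c = data[:, perm[:n1]].sum(axis=1)
        stat = np.abs((csum - c) / n2 - c / n1)
        count += stat >= obs - 1e-12
    return (count + 1.0) / (n_permutations + 1.0)


def test_per_protein(matrix: IntensityMatrix, test: str, seed: int = 0, **params) -> np.ndarray:
    """Per-protein ranking score (1 - p); higher means more evidence of
    differential abundance.

    Remaining missing entries (imputation = none) are treated as intensity 0,
    the common "missing set to zero" convention. Degenerate proteins
    (constant data, undefined p) score 0 rather than raising.
    """
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}")
    values = np.where(matrix.mask, 0.0, matrix.values)
    ctrl = values[:, matrix.ctrl_cols]
    trt = values[:, matrix.trt_cols]

    if test == "permutation":
        pvals = _permutation_pvalues(
            ctrl, trt, int(params.get("n_permutations", 1000)), seed
        )
        return 1.0 - pvals

    npr = values.shape[0]
    pvals = np.ones(npr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "t":
            res = stats.ttest_ind(trt, ctrl, axis=1, equal_var=True)
            pvals = np.asarray(res.pvalue)
        else:
            for i in range(npr):
                a, b = ctrl[i], trt[i]
                if np.ptp(np.concatenate([a, b])) == 0.0:
                    continue
                try:
                    if test == "wilcoxon_rank_sum":
                        pvals[i] = stats.ranksums(b, a).pvalue
                    elif test == "kruskal_wallis":
                        pvals[i] = stats.kruskal(b, a).pvalue
                    else:
                        pvals[i] = stats.ks_2samp(b, a).pvalue
                except ValueError:
                    pvals[i] = 1.0
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    return 1.0 - pvals
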
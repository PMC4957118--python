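"""Bayesian expected-FDR computation and threshold selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FdrCurve", "expected_fdr", "select_threshold"]


@dataclass(frozen=True)
class FdrCurve:
    """Expected FDR over the candidate threshold grid.

    ``selected_threshold`` is ``None`` when even the strictest threshold
    exceeds ``alpha_level``; ``n_called`` is then 0.
    """

    thresholds: np.ndarray
    expected_fdr: np.ndarray
    offset_c: float
    alpha_level: float
    selected_threshold: float | None
    n_called: int


def _validate(posteriors, c):
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.size == 0:
        raise ValueError("empty posterior list")
    if np.any(posteriors < 0) or np.any(posteriors > 1):
        raise ValueError("posteriors must lie in [0, 1]")
    if c < 0:
        raise ValueError("offset c must be non-negative")
    return posteriors


def expected_fdr(posteriors, p_th: float, c: float = 0.0) -> float:
    """Average posterior null probability among called proteins.

    Returns ``sum((1 - p_i) * [p_i >= p_th]) / (c + sum([p_i >= p_th]))``.
    With an empty call set the result is 0 when ``c > 0`` (offset convention)
    and NaN (undefined, with a warning) when ``c == 0``.
    """
    posteriors = _validate(posteriors, c)
    called = posteriors >= p_th
    k = int(called.sum())
    if k == 0:
        if c == 0.0:
            warnings.warn("no protein called and c = 0: expected FDR undefined")
            return float("nan")
        return 0.0
    return float((1.0 - posteriors[called]).sum() / (c + k))


def select_threshold(posteriors, alpha_level: float, c: float = 0.0) -> FdrCurve:
    """Pick the smallest threshold whose expected FDR is within the target.

    The candidate grid is the sorted unique posterior values — the expected
    FDR step function changes only there, so the grid is lossless. The call
    rule is inclusive (``p_i >= p_th``); the smallest admissible threshold
    maximizes the number of calls subject to the FDR bound.
    """
    if not 0.0 < alpha_level < 1.0:
        raise ValueError("alpha_level must lie in (0, 1)")
    posteriors = _validate(posteriors, c)
    grid = np.unique(posteriors)  # ascending
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        efdr = np.array([expected_fdr(posteriors, th, c) for th in grid])
    ok = np.flatnonzero(~np.isnan(efdr) & (efdr <= alpha_level))
    if ok.size:
        selected = float(grid[ok[0]])
        n_called = int(np.sum(posteriors >= selected))
    else:
        selected, n_called = None, 0
    return FdrCurve(grid, efdr, float(c), float(alpha_level), selected, n_called)
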
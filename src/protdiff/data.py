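"""Core data container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CTRL = "CTRL"
TRT = "TRT"


@dataclass
class IntensityMatrix:
    """A proteins x samples grid of log-intensities with explicit missingness.

    Parameters
    ----------
    values
        Float array of shape ``(n_proteins, n_samples)``. Entries flagged in
        ``mask`` are placeholders (conventionally 0) and must never be read
    mask
        Boolean array, same shape; ``True`` marks a missing entry.
    protein_ids
        Unique protein labels, length ``n_proteins``.
    group_labels
        Per-sample assignment to ``"CTRL"`` or ``"TRT"``; both groups must be
        non-empty.
    """

    values: np.ndarray
    mask: np.ndarray
    protein_ids: np.ndarray
    group_labels: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.protein_ids = np.asarray(self.protein_ids)
        self.group_labels = np.asarray(self.group_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (proteins x samples)")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")
        if len(self.protein_ids) != self.values.shape[0]:
            raise ValueError("protein_ids length does not match values")
        if len(self.protein_ids) != len(set(map(str, self.protein_ids))):
            raise ValueError("duplicate protein IDs")
        if len(self.group_labels) != self.values.shape[1]:
            raise ValueError("group_labels length does not match values")
        bad = set(self.group_labels) - {CTRL, TRT}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not (np.any(self.group_labels == CTRL) and np.any(self.group_labels == TRT)):
            raise ValueError("both CTRL and TRT groups must be non-empty")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("observed entries must be finite")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def ctrl_cols(self) -> np.ndarray:
        return np.flatnonzero(self.group_labels == CTRL)

    @property
    def trt_cols(self) -> np.ndarray:
        return np.flatnonzero(self.group_labels == TRT)

    def observed(self) -> np.ndarray:
        """Values with missing entries replaced by NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            self.mask.copy(),
            self.protein_ids.copy(),
            self.group_labels.copy(),
            dict(self.flags),
        )
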
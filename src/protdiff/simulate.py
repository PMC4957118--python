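"""Synthetic benchmark data: Normal, Gamma and Rician log-intensity matrices
with ground-truth differential labels and detection-limit censoring.

Generative design
-----------------
Each dataset holds ``n_proteins`` log-intensity rows over two groups of
``n_per_group`` samples. Per protein: a differential indicator
``lambda ~ Bernoulli(0.5)``, a direction ``delta`` uniform on {-1, +1} and an
effect magnitude ``tau ~ Gamma(shape 10, scale 0.5)`` (mean 5). The control
baseline ``mu_i`` and the sampling family vary:

* normal — ``mu_i ~ N(15, 3)`` (variance 3); entries ``N(mu, sigma^2)`` /
  ``N(mu + lambda*delta*tau, sigma^2)``.
* gamma — ``mu_i ~ Gamma(56.25, 0.2667)`` (mean 15, sd 2); group entries are
  Gamma with shape/scale moment-matched to (group mean, variance sigma^2).
* rician — ``mu_i ~ Rice(15, sigma)``; entries ``Rice(mu, sigma)`` /
  ``Rice(mu + lambda*delta*tau, sigma)``.

Detection-limit censoring then marks the globally smallest fraction of
entries as missing (stored as 0 behind the mask), coupling missingness to
abundance.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .data import CTRL, TRT, IntensityMatrix

__all__ = [
    "FAMILIES",
    "SimulationConfig",
    "GroundTruth",
    "sample_rice",
    "sample_effect_sizes",
    "sample_baselines",
    "simulate_dataset",
    "censor_detection_limit",
    "generate_benchmark_grid",
]

FAMILIES = ("normal", "gamma", "rician")

EFFECT_SHAPE, EFFECT_SCALE = 10.0, 0.5
NORMAL_MU_MEAN, NORMAL_MU_VAR = 15.0, 3.0
GAMMA_MU_SHAPE, GAMMA_MU_SCALE = 56.25, 0.2667
RICE_MU_NU = 15.0


@dataclass(frozen=True)
class SimulationConfig:
    family: str = "normal"
    n_proteins: int = 1000
    n_per_group: int = 5
    sigma: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_proteins < 1 or self.n_per_group < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Per-protein truth: 0/1 differential flag, +-1 direction, effect size."""

    lambda_: np.ndarray
    delta: np.ndarray
    tau: np.ndarray

    @property
    def effect(self) -> np.ndarray:
        """Signed true group-mean difference ``lambda * delta * tau``."""
        return self.lambda_ * self.delta * self.tau


def sample_rice(rng: np.random.Generator, nu, sigma: float, size=None) -> np.ndarray:
    """Draw from Rice(nu, sigma) as sqrt((nu + X)^2 + Y^2), X,Y ~ N(0, sigma^2)."""
    x = rng.normal(0.0, sigma, size=size)
    y = rng.normal(0.0, sigma, size=size)
    return np.sqrt((nu + x) ** 2 + y**2)


def sample_effect_sizes(rng: np.random.Generator, size) -> np.ndarray:
    """Treatment-effect magnitudes, Gamma(shape 10, scale 0.5)."""
    return rng.gamma(EFFECT_SHAPE, EFFECT_SCALE, size=size)


def sample_baselines(rng: np.random.Generator, family: str, size, sigma: float = 1.0) -> np.ndarray:
    """Control-group mean log-intensities mu_i for the given family."""
    if family == "normal":
        return rng.normal(NORMAL_MU_MEAN, np.sqrt(NORMAL_MU_VAR), size=size)
    if family == "gamma":
        return rng.gamma(GAMMA_MU_SHAPE, GAMMA_MU_SCALE, size=size)
    if family == "rician":
        return sample_rice(rng, RICE_MU_NU, sigma, size=size)
    raise ValueError(f"family must be one of {FAMILIES}")


def _gamma_moment_params(mean: np.ndarray, var: float):
    """Shape/scale so the Gamma has the requested mean and variance."""
    return mean**2 / var, var / mean


def simulate_dataset(config: SimulationConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """One reproducible dataset plus its ground truth.

    In the gamma family a treatment mean that is not positive (huge negative
    effect meeting a small baseline) cannot be moment-matched; the effect is
    resampled and the protein flagged.
    """
    rng = np.random.default_rng(config.seed)
    npr, n = config.n_proteins, config.n_per_group
    lam = rng.integers(0, 2, size=npr).astype(float)
    delta = rng.choice([-1.0, 1.0], size=npr)
    tau = sample_effect_sizes(rng, npr)
    mu = sample_baselines(rng, config.family, npr, config.sigma)
    sigma = config.sigma

    if config.family == "gamma":
        # resample tau where the implied treatment mean is non-positive
        resampled = []
        for _ in range(1000):
            bad = np.flatnonzero(mu + lam * delta * tau <= 0)
            if bad.size == 0:
                break
            resampled.extend(bad.tolist())
            tau[bad] = sample_effect_sizes(rng, bad.size)
        else:
            raise RuntimeError("gamma moment matching failed to find positive means")
        if resampled:
            warnings.warn(f"resampled effect size for {len(set(resampled))} protein(s)")

    mean_trt = mu + lam * delta * tau
    if config.family == "normal":
        ctrl = rng.normal(mu[:, None], sigma, size=(npr, n))
        trt = rng.normal(mean_trt[:, None], sigma, size=(npr, n))
    elif config.family == "gamma":
        var = sigma**2
        a_c, b_c = _gamma_moment_params(mu, var)
        a_t, b_t = _gamma_moment_params(mean_trt, var)
        ctrl = rng.gamma(a_c[:, None], b_c[:, None], size=(npr, n))
        trt = rng.gamma(a_t[:, None], b_t[:, None], size=(npr, n))
    else:
        ctrl = sample_rice(rng, mu[:, None], sigma, size=(npr, n))
        trt = sample_rice(rng, mean_trt[:, None], sigma, size=(npr, n))

    values = np.concatenate([ctrl, trt], axis=1)
    matrix = IntensityMatrix(
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        protein_ids=np.array([f"P{i:05d}" for i in range(npr)]),
        group_labels=np.array([CTRL] * n + [TRT] * n),
    )
    truth = GroundTruth(lam, delta, tau)
    if config.missing_fraction > 0:
        matrix = censor_detection_limit(matrix, config.missing_fraction)
    return matrix, truth


def censor_detection_limit(matrix: IntensityMatrix, missing_fraction: float) -> IntensityMatrix:
    """Mark the globally smallest entries missing, mimicking an MS detection
    limit.

    Exactly ``floor(missing_fraction * total)`` entries are censored, chosen
    across the whole matrix (not per protein or group); ties at the boundary
    are broken by first occurrence. Censored entries are stored as 0 behind
    the mask.
    """
    if missing_fraction >= 1.0 or missing_fraction < 0.0:
        raise ValueError("missing_fraction must lie in [0, 1)")
    if matrix.mask.any():
        raise ValueError("matrix already has missing entries")
    out = matrix.copy()
    k = int(np.floor(missing_fraction * out.values.size))
    if k == 0:
        return out
    idx = np.argsort(out.values.ravel(), kind="stable")[:k]
    mask = out.mask.ravel()
    mask[idx] = True
    out.mask = mask.reshape(out.values.shape)
    out.values[out.mask] = 0.0
    return out


def _derived_seed(base_seed: int, family: str, sigma, missing, n_per_group, replicate) -> int:
    key = f"{family}|{sigma}|{missing}|{n_per_group}|{replicate}".encode()
    return (int(base_seed) + zlib.crc32(key)) % (2**32)


def generate_benchmark_grid(
    families=FAMILIES,
    sigmas=(1.0, 2.0, 3.0),
    missing_fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    sample_sizes=(5, 25),
    n_replicates: int = 100,
    base_seed: int = 0,
    n_proteins: int = 1000,
    materialize: bool = True,
):
    """Yield the full factorial design as ``(SimulationConfig, dataset)``.

    ``dataset`` is a ``(IntensityMatrix, GroundTruth)`` pair, or ``None``
    when ``materialize=False`` (cheap enumeration). Per-dataset seeds are
    derived deterministically from the base seed and the factor tuple so any
    cell is recomputable in isolation.
    """
    for family, sigma, missing, size in itertools.product(
        families, sigmas, missing_fractions, sample_sizes
    ):
        for rep in range(n_replicates):
            config = SimulationConfig(
                family=family,
                n_proteins=n_proteins,
                n_per_group=size,
                sigma=sigma,
                missing_fraction=missing,
                seed=_derived_seed(base_seed, family, sigma, missing, size, rep),
                n_replicates=1,
            )
            yield config, (simulate_dataset(config) if materialize else None)
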
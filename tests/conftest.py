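import numpy as np
import pytest

from protdiff.data import CTRL, TRT, IntensityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, mask=None, groups=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    if groups is None:
        half = values.shape[1] // 2
        groups = [CTRL] * half + [TRT] * (values.shape[1] - half)
    ids = np.array([f"P{i}" for i in range(values.shape[0])])
    return IntensityMatrix(values, np.asarray(mask, dtype=bool), ids, np.asarray(groups))


@pytest.fixture
def small_matrix(rng):
    """8 proteins x 6 samples (3 CTRL + 3 TRT) with a few missing entries."""
    values = rng.normal(0.0, 1.0, size=(8, 6))
    mask = np.zeros((8, 6), dtype=bool)
    mask[0, 1] = True
    mask[3, 4] = True
    mask[5, 0] = True
    mask[5, 5] = True
    values[mask] = 0.0
    return make_matrix(values, mask)
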
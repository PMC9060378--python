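"""Shared fixtures: tiny toy samples and a session-scoped trained bundle."""

import numpy as np
import pytest

from singanseg.fixtures import make_toy_dataset
from singanseg.io_types import PyramidConfig, build_pyramid
from singanseg.model_core import ScaleModelConfig, TrainConfig, train_pyramid


TINY_SCALE_CFG = ScaleModelConfig(base_channels=8)
TINY_TRAIN_CFG = TrainConfig(epochs_per_scale=25, seed=3)
TINY_PYR_CFG = PyramidConfig(scale_factor=0.55, min_size=16, max_size=32)


@pytest.fixture(scope="session")
def toy_sample():
    return make_toy_dataset(1, (32, 32), seed=7)[0]


@pytest.fixture(scope="session")
def toy_pyramid(toy_sample):
    return build_pyramid(toy_sample, TINY_PYR_CFG)


@pytest.fixture(scope="session")
def tiny_bundle(toy_pyramid):
    """A small trained pyramid shared across tests (trained once per run)."""
    return train_pyramid(toy_pyramid, TINY_SCALE_CFG, TINY_TRAIN_CFG)


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    for i in np.ndindex(x.shape):
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
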
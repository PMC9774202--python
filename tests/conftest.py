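import numpy as np
import pytest

from fedprune.graph import init_params
from fedprune.ir import Conv, Dense, GlobalAvgPool, ModelSpec, Pool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A minimal two-conv classifier used across the unit tests."""
    return ModelSpec("tiny", (16, 16, 3), 4, [
        Conv("c1", 6),
        Pool(),
        Conv("c2", 8),
        GlobalAvgPool(),
        Dense("head", 4),
    ])


@pytest.fixture
def tiny_params(tiny_spec):
    return init_params(tiny_spec, rng_seed=0)


@pytest.fixture
def tiny_data(rng):
    """A small linearly separable 2-class-style image set (4 classes by brightness)."""
    X, y = [], []
    for c in range(4):
        base = 0.15 + 0.2 * c
        X.append(np.clip(base + 0.03 * rng.standard_normal((12, 16, 16, 3)), 0, 1))
        y.append(np.full(12, c))
    return np.concatenate(X), np.concatenate(y)
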
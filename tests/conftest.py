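import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_unit_pair(rng):
    """A pair of same-shape random images with values in [0, 1]."""

    def make(shape=(64, 64)):
        return rng.uniform(size=shape), rng.uniform(size=shape)

    return make


@pytest.fixture
def clean_scene():
    """A disturbance-free synthetic canopy scene with one mature fruit."""
    from fruitfuse import generate_batch

    return generate_batch(1, "none", seed=11)[0]
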
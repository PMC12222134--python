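import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    """Seeded 24 x 32 RGB image with full [0, 1] dynamic range."""
    return rng.random((24, 32, 3))


def constant_image(value, shape=(16, 16)):
    return np.full(shape + (3,), value, dtype=float)
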
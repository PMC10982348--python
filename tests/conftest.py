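import numpy as np
import pytest

from cornseg import (
    SegConfig,
    clean_phantom_spec,
    make_phantom_2d,
    noisy_phantom_spec,
)


@pytest.fixture(scope="session")
def cfg():
    return SegConfig()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless 3-interface phantom (the canonical clean study scan)."""
    spec = clean_phantom_spec(seed=1)
    image, truth = make_phantom_2d(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = noisy_phantom_spec(seed=7)
    image, truth = make_phantom_2d(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
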
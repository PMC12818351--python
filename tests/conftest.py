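import numpy as np
import pytest

import fmbayes as fb


@pytest.fixture(scope="session")
def toy_small():
    """30-state, 20-observable clean toy dataset (fast unit-test scale)."""
    return fb.build_toy_dataset(30, 20, seed=11)


@pytest.fixture(scope="session")
def toy_noisy(toy_small):
    return fb.add_noise(toy_small, 0.5, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
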
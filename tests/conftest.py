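import numpy as np
import pytest

from nsdohmix.mixture import MixturePrior


@pytest.fixture
def toy_unit_prior():
    """Uniform-ish prior at small truncation, handy for enumeration checks."""
    return MixturePrior(lam=1.0, k_max=3, gamma=1.0, alpha=1.0, beta=1.0)


@pytest.fixture
def toy_matrix_4x2():
    return np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=np.uint8)


@pytest.fixture
def toy_matrix_5x2():
    return np.array([[1, 0], [0, 1], [1, 1], [0, 0], [1, 0]], dtype=np.uint8)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
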
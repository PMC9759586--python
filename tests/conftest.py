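import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_items(rng, n_items, n_units):
    """Random item vectors with i.i.d. Normal(0, 1/N) components."""
    return rng.normal(0.0, 1.0 / np.sqrt(n_units), (n_items, n_units))
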
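import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_pair():
    """One deterministic 24^3 synthetic pair shared across tests."""
    from wavemorph.synthetic import make_pair
    return make_pair(3, (24, 24, 24), n_labels=3, amplitude=2.0)
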
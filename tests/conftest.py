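import numpy as np
import pytest
from hypothesis import settings

from pitiming import GeneratorParams

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return GeneratorParams(seed=7)


@pytest.fixture
def probe_params():
    """PI/PIN-only sessions as used in the distracter experiments."""
    return GeneratorParams(n_fi=0, n_pi=20, n_pin=6, seed=7)
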
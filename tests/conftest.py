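import numpy as np
import pytest
from hypothesis import settings

from wardsim.fixtures import default_mmh_config

settings.register_profile("deterministic", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mmh_config():
    """Baseline ward configuration (90 days, 50 trials)."""
    return default_mmh_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
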
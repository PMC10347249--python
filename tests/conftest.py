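import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synth_config():
    """A fast synthetic bundle: 2 stations, 2 years."""
    from deltacrop.synthetic import SyntheticConfig

    return SyntheticConfig(seed=11, n_stations=2, years=(2000, 2001))
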
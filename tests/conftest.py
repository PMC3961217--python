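import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A one-plate screen small enough for per-test simulation."""
    from senscreen import SimulationConfig

    return SimulationConfig(
        n_library_mirnas=80,
        replicates_per_mirna=4,
        wells_per_plate=384,
        rng_seed=7,
    )
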
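import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from traceblink.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One fully simulated final-day session (conditioning + extinction),
    small enough to share across tests."""
    cfg = SimConfig(n_cells=40, seed=3)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
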
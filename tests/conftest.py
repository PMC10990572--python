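import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ou_env():
    from mottrack import EnvironmentConfig
    return EnvironmentConfig(
        dynamics_kind="ou", sigma=2.0, arena=(240.0, 240.0),
        updates_per_second=20.0, n_updates=60, min_distance=0.0,
        n_targets=2, n_objects=6)
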
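import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trailmap import RoutingParams, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast community: 50 agents, 5 virtual days, brisk arrivals."""
    return SimulationConfig(
        n_agents=50,
        seeker_proportion=0.2,
        helper_proportion=0.8,
        duration_hours=120.0,
        request_rate_per_seeker_per_day=4.0,
        interaction_duration_mean_min=6.0,
        routing=RoutingParams(),
        seed=7,
    )
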
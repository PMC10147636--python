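import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Reduced two-group, one-time-point cohort used across the statistical tests."""
    from rsconn.simulate import SimulationConfig

    return SimulationConfig(
        n_nodes=30,
        n_communities=3,
        n_timepoints_signal=150,
        group_sizes={"AN": 12, "HC": 14},
        time_points={"AN": ("TP1", "TP2"), "HC": ("TP1", "TP2")},
        base_connectivity={"AN": 0.29, "HC": 0.33},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    from rsconn.simulate import simulate_cohort

    return simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
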
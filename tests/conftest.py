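import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kcvgate import GatingScheme, SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_state_scheme() -> GatingScheme:
    """Single slow closed state, 3:1 open:closed occupancy."""
    return GatingScheme({"C1": (100.0, 300.0)}, i_true=6.0)


@pytest.fixture(scope="session")
def three_closed_scheme() -> GatingScheme:
    """The reference slow scheme: C1 (1 ms), C2 (20 ms), C3 (300 ms)."""
    return GatingScheme({"C1": (50.0, 1000.0), "C2": (5.0, 50.0),
                         "C3": (0.5, 1.0 / 0.3)}, i_true=11.0)


@pytest.fixture(scope="session")
def slow_trace(three_closed_scheme):
    """A 60-s noisy recording of the reference slow scheme at +120 mV."""
    from kcvgate import simulate_trace
    cfg = SimulationConfig(duration=60.0, noise_sd=0.8, voltage=120.0,
                           seed=42, oversample=10)
    return simulate_trace(three_closed_scheme, cfg)
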
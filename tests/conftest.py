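import numpy as np
import pytest

from glancecf.environment import SimulationConfig, generate_leader_profile
from glancecf.params import DriverParams, PerceptionParams


@pytest.fixture
def driver_params():
    """Mid-range non-crashing driver parametrization."""
    return DriverParams.with_calibrated(T=1.5, a_max=1.5, sigma_a_star=1.0)


@pytest.fixture
def perception_params():
    return PerceptionParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_profile():
    """A 30-second single-target leader profile for quick closed-loop runs."""
    from glancecf.environment import LeaderProfile
    return LeaderProfile(segments=((0.0, 40.0 / 3.6),), ramp_accel=2.0,
                         protocol="real_car", duration=30.0)


@pytest.fixture
def vr_profile():
    return generate_leader_profile("vr", np.random.default_rng(42))


@pytest.fixture
def sim_config():
    return SimulationConfig()
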
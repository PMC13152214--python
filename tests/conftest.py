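import math

import pytest
from hypothesis import HealthCheck, settings

from neuroscale import AnimalParams, TaskConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_swing_plant() -> AnimalParams:
    """Gravity-free unit plant of the normalized system (no force limit)."""
    return AnimalParams(
        task="swing",
        body_mass=1.0,
        t_sm=1.0,
        inertia=1.0,
        l_com=1.0,
        tau_iso=math.inf,
        limb_mass=0.0,
        g=0.0,
    )


@pytest.fixture(scope="session")
def unit_swing_cfg() -> TaskConfig:
    """Normalized swing step: rest at 0 to rest at the unit reference."""
    return TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
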
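import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rrlogistic import (
    DemographyParams,
    DispersalSpec,
    Domain,
    KernelSpec,
    MovementParams,
    SimConfig,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def domain() -> Domain:
    return Domain(L=1.0)


@pytest.fixture
def kernel() -> KernelSpec:
    """Short-range competition at the scale used throughout the study."""
    return KernelSpec(sigma_q=0.01)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_config(
    mode: str = "SESSILE",
    sigma_q: float = 0.01,
    sigma_d: float = 0.1,
    n0: int = 700,
    events: int = 200_000,
    b: float = 1.5,
    d0: float = 0.1,
    gamma: float = 0.002,
    L: float = 1.0,
    dispersal_family: str = "gaussian",
    **movement,
) -> SimConfig:
    """Study-condition configuration with selective overrides."""
    return SimConfig(
        domain=Domain(L=L),
        demography=DemographyParams(
            b=b,
            d0=d0,
            gamma=gamma,
            kernel=KernelSpec(sigma_q=sigma_q),
            dispersal=DispersalSpec(sigma_d=sigma_d, family=dispersal_family),
        ),
        movement=MovementParams(mode=mode, **movement),
        n0=n0,
        events=events,
    )


@pytest.fixture
def small_sessile_config() -> SimConfig:
    return make_config(n0=50, events=300)
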
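import numpy as np
import pytest
from hypothesis import settings

from conjphage import KineticParameters, integrate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from conjphage.simulate import preset_condition


@pytest.fixture(scope="session")
def params():
    """Published default parameter set."""
    return KineticParameters()


@pytest.fixture(scope="session")
def cond1_donor_traj(params):
    """Pure-donor conjugation-only trajectory (700 min, 20-min sampling)."""
    return integrate(preset_condition("COND1", 0), params,
                     system="conjugation_only")


@pytest.fixture(scope="session")
def cond2c_traj(params):
    """Pre-infected culture, infection-only system (500 min)."""
    return integrate(preset_condition("COND2C", 0), params,
                     system="infection_only")


@pytest.fixture(scope="session")
def cond3_traj(params):
    """Competition trajectory, 1:10 donor:recipient mixture plus phage."""
    return integrate(preset_condition("COND3", 2), params, system="full")
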
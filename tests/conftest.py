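import numpy as np
import pytest

from coilcal.fieldmodel import CoilModelSet
from coilcal.simulate import default_shield_scenario, fit_coil_models


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220415)


@pytest.fixture(scope="session")
def fluxgate_scenario():
    """Default synthetic shield scenario in fluxgate mode (17 usable coils)."""
    return default_shield_scenario(seed=7, mode="fluxgate")


@pytest.fixture(scope="session")
def coil_models(fluxgate_scenario) -> CoilModelSet:
    """lmax=5 VSH models of the 17 active coils, fitted from the noiseless
    108-point triaxial field maps."""
    return fit_coil_models(fluxgate_scenario, lmax=5)
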
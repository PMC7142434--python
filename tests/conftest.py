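import numpy as np
import pytest

from fishnmr.profiles import TREATMENT_PROFILES
from fishnmr.synthetic import AcquisitionSpec, RelaxComponent, simulate_cpmg_decay


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def control_profile():
    return TREATMENT_PROFILES["control"]


@pytest.fixture(scope="session")
def frying_profile():
    return TREATMENT_PROFILES["frying"]


def profile_components(profile, mass_g=1.0):
    """Three noiseless components at a profile's mean pool parameters."""
    return [
        RelaxComponent(t2_ms=float(t2), amplitude=float(a) * mass_g)
        for t2, a in zip(profile.pool_t2_means, profile.pool_area_means)
    ]


@pytest.fixture(scope="session")
def control_decay(acq, control_profile):
    return simulate_cpmg_decay(profile_components(control_profile), acq, noise_sd=0.0)


@pytest.fixture(scope="session")
def frying_decay(acq, frying_profile):
    return simulate_cpmg_decay(profile_components(frying_profile), acq, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
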
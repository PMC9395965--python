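import numpy as np
import pytest

from psmcea.calibrate import calibrate_base_case
from psmcea.ipd import default_scenario, simulate_trial


@pytest.fixture(scope="session")
def trial_ipd():
    """A moderate synthetic trial (1,000/arm) under the default study conditions."""
    return simulate_trial(default_scenario(n_per_arm=1000, seed=11))


@pytest.fixture(scope="session")
def model():
    """The calibrated base-case model."""
    return calibrate_base_case()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
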
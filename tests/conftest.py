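import numpy as np
import pytest

from gaitwnn import generate_cohort, trial_to_cycle
from gaitwnn.gi_features import cycle_to_sample


@pytest.fixture(scope="session")
def small_cohort():
    """Six noisy trials (2 subjects x 3 trials)."""
    return generate_cohort(2, 3, seed=11, noise_sd=0.02)


@pytest.fixture(scope="session")
def default_cycle(small_cohort):
    """One normalized gait cycle from the small cohort."""
    return trial_to_cycle(small_cohort[0])


@pytest.fixture(scope="session")
def default_sample(default_cycle):
    """(features, targets, schedule) of the default cycle."""
    return cycle_to_sample(default_cycle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
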
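import dataclasses

import numpy as np
import pytest

from cbeqc.profiles import CohortSpec, reference_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Short cohort spec with no powerline or baseline noise."""
    return CohortSpec(n_participants=4, reps_per_condition=2, trial_duration=4.0,
                      bursts_per_trial=4, powerline_amplitude=0.0, noise_sd=0.0, seed=7)


@pytest.fixture
def noiseless_m5():
    """M5 correct profile with all variance switched off."""
    p = reference_profile("M5", "correct")
    return dataclasses.replace(p, angle_sd_between=0.0, angle_sd_within=0.0)
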
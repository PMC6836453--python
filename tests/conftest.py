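import numpy as np
import pytest

import synergait as sg
from synergait import signal_prep


@pytest.fixture(scope="session")
def template():
    return sg.default_template()


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects, 4 strides at 200 Hz: cheap input for downstream stages."""
    cfg = sg.CohortConfig(
        n_subjects=3, strides_per_subject=4, sampling_rate_hz=200.0, seed=42
    )
    return sg.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def truth_mean_profiles(subject) -> np.ndarray:
    """Subject's mean 200-sample profiles computed from ground-truth H."""
    profs = []
    for k, H in enumerate(subject.H_true):
        b = subject.phase_bounds_samples[k]
        profs.append(signal_prep.time_normalize(H, b - b[0]).values)
    return np.mean(profs, axis=0)
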
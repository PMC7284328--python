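import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import detect_ecg as d

settings.register_profile(
    "suite", max_examples=20, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_morphology():
    """A jitter-free textbook morphology at 60 bpm."""
    return d.SubjectMorphology(
        subject_id="ref",
        wave_amplitudes={"P": 0.15, "Q": -0.1, "R": 1.0, "S": -0.2, "T": 0.3},
        wave_widths={"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.05},
        wave_offsets={"P": -0.18, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.25},
        mean_heart_rate=60.0,
        heart_rate_jitter_sd=0.0,
        amplitude_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small deterministic cohort used by several modules' tests."""
    return d.sample_cohort(5, 60.0, 200.0, seed=7, noise=d.ZERO_NOISE)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
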
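import pytest

from respmotion.experiment import cohort_windows
from respmotion.simulate import (
    WaveformConfig,
    generate_cohort,
    generate_trace,
    sample_profile,
)


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless waveform configuration for analytic checks."""
    return WaveformConfig(
        marker_noise_sd=0.0, lateral_jitter_sd=0.0, tumor_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def regular_profile():
    return sample_profile("regular", "normal", seed=1, subject_id="SUBJ")


@pytest.fixture(scope="session")
def clean_trace(regular_profile, clean_config):
    """Noiseless regular trace: 20 s at the profile's breathing rate."""
    return generate_trace(regular_profile, clean_config, duration=20.0, seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """6 regular subjects x 4 repeats — quick end-to-end material."""
    return generate_cohort(n_regular=6, n_irregular=0, repeats=4, seed=5)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    return cohort_windows(small_cohort)
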
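import numpy as np
import pytest

from neurofuse import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A fast cohort: 6+6 subjects, 8 s of EEG/video, 40 fixations."""
    return CohortSpec(n_asd=6, n_td=6, seed=7, eeg_duration_s=8.0,
                      video_duration_s=8.0, n_fixations=40)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
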
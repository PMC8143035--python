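import numpy as np
import pytest
from hypothesis import settings

from wbvphysio.config import CohortConfig

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Three subjects with short records: fast, but every epoch present."""
    return CohortConfig(
        n_subjects=3,
        seed=7,
        accel_duration=16.0,
        emg_pre_onset=2.0,
        emg_post_onset=72.0,
        baseline_duration=300.0,
        vibration_duration=600.0,
    )
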
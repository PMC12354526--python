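import numpy as np
import pytest

from osascreen.cohort import CohortConfig, simulate_cohort
from osascreen.preprocessing import PreprocessConfig, build_features
from osascreen.training import split_subjects


@pytest.fixture(scope="session")
def small_cohort():
    """Eight subjects, 4 channels, 150 s: four 60-s windows each at 50% overlap."""
    config = CohortConfig(n_subjects=8, channels=4, duration=150.0, seed=3)
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """(train, eval) window datasets from the small cohort, CSP m=2."""
    _, recordings = small_cohort
    subject_labels = {r.subject_id: r.label for r in recordings}
    train_subjects, _ = split_subjects(subject_labels, 0.25, seed=0)
    config = PreprocessConfig(csp_filters_per_end=2)
    return build_features(recordings, config, train_subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
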
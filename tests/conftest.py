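import numpy as np
import pytest

from facescreen.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_au_cohort():
    """Tiny AU-only cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_subjects_per_class=4,
        sessions_per_subject_range=(1, 2),
        frames_per_session=256,
        seed=42,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
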
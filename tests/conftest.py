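import numpy as np
import pytest
from hypothesis import settings

import sonictal as s

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """One-group cohort small enough to render in a few seconds."""
    return s.CohortConfig(
        groups=("PHT+FUS",),
        n_per_group=2,
        sessions_per_period=2,
        session_hours=0.1,
        event_rate_mean={"PHT+FUS": 10.0},
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    records, truth = s.generate_cohort(tiny_cohort_config)
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
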
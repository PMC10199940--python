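import numpy as np
import pytest

from eegmarkers import CohortSpec, generate_cohort, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small single-channel cohort spec used across evaluation tests."""
    return CohortSpec(n_healthy=10, n_ad=10, n_channels=1, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def one_record():
    spec = CohortSpec(n_healthy=1, n_ad=1, n_channels=3, seed=11)
    return generate_subject(spec, "A", 0)
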
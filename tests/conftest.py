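import numpy as np
import pytest
from hypothesis import settings

from improve_cea import CohortSpec, default_parameters, generate_cohort
from improve_cea.pipeline import seed_streams

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def cohort(params):
    """The default 678-patient synthetic cohort at the reference seed."""
    return generate_cohort(CohortSpec(), params.improve, seed_streams(0)["cohort"])


@pytest.fixture(scope="session")
def small_cohort(params):
    """A 150-patient cohort for the slower end-to-end checks."""
    return generate_cohort(
        CohortSpec(n=150), params.improve, seed_streams(7)["cohort"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
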
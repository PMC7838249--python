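import numpy as np
import pytest

from alexidom import default_group_specs, generate_cohort, score_cohort


@pytest.fixture(scope="session")
def default_specs():
    return default_group_specs()


@pytest.fixture(scope="session")
def cohort_400(default_specs):
    """One default-size (281 + 119) item-level synthetic cohort."""
    return generate_cohort(default_specs, seed=7)


@pytest.fixture(scope="session")
def scored_400(cohort_400):
    return score_cohort(cohort_400)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
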
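import numpy as np
import pytest

from emobias import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by read-only tests."""
    return generate_cohort(CohortSpec(n_per_cell=15, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
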
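import numpy as np
import pytest

from gratiokit.acquisition import DEFAULT_PROTOCOL
from gratiokit.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def acq():
    return DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-arm cohort reused by read-only tests."""
    return generate_cohort(CohortConfig(n_patients=8, n_controls=6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
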
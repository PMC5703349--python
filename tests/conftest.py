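import numpy as np
import pytest

from epimediate import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared by read-only tests."""
    params = SimParams(n_samples=400, n_cpgs=60, seed=7)
    cohort, truth = simulate_cohort(params)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
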
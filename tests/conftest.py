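import numpy as np
import pytest

from numsense import CohortConfig, generate_cohort, make_levels


@pytest.fixture(scope="session")
def default_levels():
    return make_levels(8, 32, 11)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort, shared across tests (read-only)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def fast_cohort():
    """Small cohort without trial simulation, for cheap structural tests."""
    return generate_cohort(CohortConfig(seed=3, simulate_trials=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
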
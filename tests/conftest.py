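import numpy as np
import pytest

from photoglu import SyntheticConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 4-subject cohort shared by read-only tests."""
    return simulate_cohort(SyntheticConfig(n_subjects=4, seed=7))


@pytest.fixture(scope="session")
def session_grid():
    """The default 1 Hz event-anchored grid, [-25, +90] min."""
    return SyntheticConfig().t
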
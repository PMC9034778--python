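import numpy as np
import pytest

from conflictdm.synth import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale default synthetic cohort (8 subjects x 20 trials)."""
    return simulate_cohort(CohortConfig(seed=123))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortConfig(n_subjects=3, n_trials=6, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
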
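import numpy as np
import pytest

from vplsearch import CohortSpec, ReliabilityPair, SearchConfig, generate_cohort


@pytest.fixture
def config():
    return SearchConfig()


@pytest.fixture
def rel():
    return ReliabilityPair(sigma_target=4.0, sigma_distractor=8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort: 3 observers/group, 3 training days + test, 120 trials."""
    spec = CohortSpec(
        n_per_group=3, n_training_sessions=3, trials_per_session=120, seed=42
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-design cohort (2x5 observers, 6 training days + test, 540 trials)."""
    return generate_cohort(CohortSpec(seed=7))
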
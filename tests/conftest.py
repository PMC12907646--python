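import numpy as np
import pandas as pd
import pytest

from vfsim import DistributionConfig, LONG_TERM, SHORT_TERM, sample_population, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """300 subjects from the default parameter distributions."""
    gen = np.random.default_rng(5)
    return sample_population(DistributionConfig(), 300, gen)


@pytest.fixture(scope="session")
def small_long_cohort(small_population):
    return simulate_cohort(small_population, LONG_TERM, np.random.SeedSequence(7))


@pytest.fixture(scope="session")
def small_short_cohort(small_population):
    return simulate_cohort(small_population, SHORT_TERM, np.random.SeedSequence(8))
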
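import numpy as np
import pytest

import trajlens as tl


@pytest.fixture(scope="session")
def grid():
    return tl.default_grid()


@pytest.fixture(scope="session")
def toy_lex():
    return tl.toy_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """A 1200-user cohort from the canonical two-group generative model."""
    spec = tl.study_generative_spec(n_users=1200, seed=202)
    return tl.simulate_study_cohort(spec), spec


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """A 2-group cubic fit on the small cohort (shared across tests)."""
    cohort, spec = small_cohort
    mspec = tl.TrajectorySpec.cubic(2, spec.time_codes)
    return tl.fit(cohort.counts, mspec, n_starts=3, seed=5)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    cohort, spec = small_cohort
    return tl.simulate_features(cohort)
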
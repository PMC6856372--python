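import numpy as np
import pytest

from figground import build_frequency_grid, default_cohort_spec, generate_cohort, load_fixture_track


@pytest.fixture(scope="session")
def grid():
    return build_frequency_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_track():
    return load_fixture_track("synthetic_sentence_42bins.csv")


@pytest.fixture(scope="session")
def cohort_df():
    """A mid-sized synthetic cohort shared across analysis tests."""
    return generate_cohort(default_cohort_spec(n=400), seed=777).table
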
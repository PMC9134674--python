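import numpy as np
import pytest

from fivea import generate_exact_table_cohort, score_cohort


@pytest.fixture(scope="session")
def exact_cohort():
    """The deterministic cohort reproducing the published band x outcome table."""
    return generate_exact_table_cohort()


@pytest.fixture(scope="session")
def scored_exact(exact_cohort):
    return score_cohort(exact_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231139)
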
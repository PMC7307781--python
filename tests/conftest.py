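import numpy as np
import pytest

from sfrtkit.cohort import CohortConfig, emit_cohort
from sfrtkit.design import study_arm_table


@pytest.fixture(scope="session")
def arm_table():
    return study_arm_table()


@pytest.fixture(scope="session")
def default_cohort():
    """One default six-arm synthetic cohort at a fixed seed."""
    return emit_cohort(CohortConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
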
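import numpy as np
import pytest

from adaptmatch.cohort import OutcomeModel, recruit_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def medium_cohort():
    """150 controls + 75 treated, the default interim configuration."""
    gen = np.random.default_rng(42)
    return recruit_cohort(150, 75, OutcomeModel(), gen)
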
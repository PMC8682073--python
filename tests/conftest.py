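import numpy as np
import pytest

from vascbayes import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default (null-association) scenario."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
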
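import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from restless_bandits import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-condition cohort used by several classification/likelihood tests."""
    spec = CohortSpec(n_subjects=3, conditions=("placebo",), seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
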
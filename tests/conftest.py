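import warnings

import numpy as np
import pytest

from telomethyl.simulate import SimConfig, generate_cohort

# convergence chatter from deliberately extreme toy designs is not a failure
warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale planted cohort shared by read-only tests."""
    return generate_cohort(SimConfig(n_samples=150, n_cpgs=400, n_blocks=50,
                                     n_true_main=5, n_true_inter=1, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
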
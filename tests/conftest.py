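import numpy as np
import pytest

from djin import synthetic


@pytest.fixture(scope="session")
def truth6():
    """A 6-variable sparse ground truth (6 directed edges)."""
    return synthetic.sample_ground_truth(6, 0.2, np.random.default_rng(7))


@pytest.fixture(scope="session")
def cohort6(truth6):
    """A small simulated cohort used across unit tests."""
    return synthetic.simulate_cohort(truth6, 250, 12.0, 0.25,
                                     np.random.default_rng(8))
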
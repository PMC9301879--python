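import numpy as np
import pytest

from ventriloquo import LikelihoodParams, PriorParams
from ventriloquo.cohort import make_profile, simulate_participant


@pytest.fixture(scope="session")
def unit_params():
    """Unit-SD likelihoods and prior centred at zero."""
    return LikelihoodParams(0.0, 1.0, 0.0, 1.0), PriorParams(0.0, 1.0, 0.5)


@pytest.fixture(scope="session")
def sc_dataset():
    """One deterministic sighted-control participant (CI-PM observer)."""
    profile = make_profile("SC01", "SC", seed=11, jitter=0.0)
    return simulate_participant(profile)


@pytest.fixture(scope="session")
def sc_frame(sc_dataset):
    return sc_dataset.to_frame()


@pytest.fixture(scope="session")
def clean_block1_frame():
    """Block 1 data from a static observer (no trial-history term)."""
    over = {"history": {"gain_A": 0.0, "gain_V": 0.0, "decay": 1.0}}
    profile = make_profile("SC02", "SC", seed=23, overrides=over, jitter=0.0)
    frame = simulate_participant(profile).to_frame()
    return frame[frame["block"] == 1]
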
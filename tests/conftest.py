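import numpy as np
import pytest

from curescore import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_dataset(rng, n=20, censor_frac=0.3):
    """Small random two-group dataset with continuous (tie-free) times."""
    time = rng.exponential(1.0, size=n)
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    group = (np.arange(n) % 2).astype(int)
    if event.sum() == 0:
        event[0] = 1
    return SurvivalDataset(time, event, group)


@pytest.fixture
def dataset_factory(rng):
    def make(n=20, censor_frac=0.3):
        return random_dataset(rng, n=n, censor_frac=censor_frac)

    return make
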
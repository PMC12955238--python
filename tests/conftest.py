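import numpy as np
import pytest

from gazediet.synthetic_data import FixtureSet, make_fixture_set


@pytest.fixture(scope="session")
def fixtures() -> FixtureSet:
    """Small canonical synthetic bundle shared across the suite."""
    return make_fixture_set(seed=7, n_frames=3000, height=64, width=84)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
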
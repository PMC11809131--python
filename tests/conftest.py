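import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bcalign.fixtures import FixtureSpec, make_pair


@pytest.fixture(scope="session")
def helix_pair():
    return make_pair(FixtureSpec("helix", 30, seed=1))


@pytest.fixture(scope="session")
def chirality_pair():
    return make_pair(FixtureSpec("loop_chirality_pair"))


@pytest.fixture(scope="session")
def blocked_chirality_pair():
    return make_pair(FixtureSpec("loop_chirality_pair", blocked=True))


@pytest.fixture(scope="session")
def threading_pair():
    return make_pair(FixtureSpec("threading_pair"))


@pytest.fixture(scope="session")
def displacement_pair():
    return make_pair(FixtureSpec("loop_displacement_pair", 40))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
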
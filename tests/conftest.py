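import numpy as np
import pytest

from swarmforage import make_arena, make_strategy


@pytest.fixture(scope="session")
def sloped_arena():
    return make_arena("sloped")


@pytest.fixture(scope="session")
def flat_arena():
    return make_arena("flat")


@pytest.fixture(scope="session")
def roles():
    return {r: make_strategy(r) for r in ("dropper", "collector", "generalist")}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
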
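import numpy as np
import pytest
from hypothesis import settings

from neurodyn import SymbolStream, TeamStream

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")

SYMS = np.array([-1, 1, 3], dtype=np.int8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_member_stream(rng, n=300, **coords):
    return SymbolStream(symbols=SYMS[rng.integers(0, 3, n)], **coords)


def random_team_stream(rng, n=300, k=2):
    return TeamStream(symbols=rng.integers(1, 3 ** k + 1, n),
                      member_ids=tuple(f"M{i+1}" for i in range(k)))


@pytest.fixture
def member_stream(rng):
    return random_member_stream(rng)


@pytest.fixture
def dyad(rng):
    a = random_member_stream(rng, member="A", channel="C3", bin_hz=10.0)
    b = random_member_stream(rng, member="B", channel="C3", bin_hz=10.0)
    return a, b
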
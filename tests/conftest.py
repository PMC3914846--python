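import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracles module importable from every test file
sys.path.insert(0, str(Path(__file__).parent))

from upep import FixtureSpec, make_transcript_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_pair():
    """One transcript pair under default generator settings, shared by
    read-only tests."""
    return make_transcript_pair(FixtureSpec(seed=11))


def random_nt(rng, n: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=n))
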
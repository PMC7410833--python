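import numpy as np
import pytest

from rbpatlas.simulate import make_transcriptome


@pytest.fixture(scope="session")
def small_world():
    """A 30-gene annotation plus repeat DB shared by read-level tests."""
    return make_transcriptome(30, 4, seed=7)


@pytest.fixture(scope="session")
def annotation(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def repeat_db(small_world):
    return small_world[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
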
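import numpy as np
import pytest

from meshrna.energy import PAIRSUM, STACKING
from meshrna.seq import RnaSequence


@pytest.fixture(scope="session")
def pairsum():
    return PAIRSUM


@pytest.fixture(scope="session")
def stacking():
    return STACKING


@pytest.fixture(params=["pairsum", "stacking"])
def model(request, pairsum, stacking):
    """Run a test under both energy-model kinds."""
    return pairsum if request.param == "pairsum" else stacking


@pytest.fixture
def random_seq():
    """Factory for seeded random RNA sequences."""

    def make(n, seed, alphabet="ACGU", p=None):
        rng = np.random.default_rng(seed)
        return RnaSequence.from_string(
            "".join(rng.choice(list(alphabet), size=n, p=p)), id=f"rand{seed}"
        )

    return make
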
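import numpy as np
import pytest

from pspabc.model import build_simplified_net, initial_marking
from pspabc.petri import PetriNet


@pytest.fixture(scope="session")
def psp_net():
    return build_simplified_net()


@pytest.fixture(scope="session")
def m0():
    return initial_marking()


@pytest.fixture()
def fig8_net():
    """The 2 H2 + O2 -> 2 H2O textbook net (3 places, 1 transition)."""
    return PetriNet(
        places=("H2", "O2", "H2O"),
        transitions=("tr1",),
        pre=[[2, 1, 0]],
        post=[[0, 0, 2]],
    )


def random_net(rng: np.random.Generator, max_places: int = 5, max_transitions: int = 5,
               max_weight: int = 3) -> PetriNet:
    """A small random net for property/oracle tests."""
    n = int(rng.integers(1, max_places + 1))
    m = int(rng.integers(1, max_transitions + 1))
    pre = rng.integers(0, max_weight + 1, size=(m, n))
    post = rng.integers(0, max_weight + 1, size=(m, n))
    test = (rng.random((m, n)) < 0.15).astype(np.int64)
    return PetriNet(
        tuple(f"p{i}" for i in range(n)),
        tuple(f"t{i}" for i in range(m)),
        pre,
        post,
        test,
    )
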
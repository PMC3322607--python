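import numpy as np
import pytest

from xrayval.geometry import (
    GeometryDictionary, RamachandranRegions, RotamerLibrary,
)
from xrayval.model_io import Atom, Chain, Residue, Structure
from xrayval.synthetic import make_helix


@pytest.fixture(scope="session")
def gdict():
    return GeometryDictionary.load()


@pytest.fixture(scope="session")
def regions():
    return RamachandranRegions.load()


@pytest.fixture(scope="session")
def rotlib():
    return RotamerLibrary.load()


@pytest.fixture(scope="session")
def helix10():
    return make_helix(10)


def random_structure(n_atoms: int, seed: int, box: float = 15.0,
                     elements=("C", "N", "O")) -> Structure:
    """Random unconnected atoms spread over a box (clash/partition tests)."""
    rng = np.random.default_rng(seed)
    ch = Chain("A")
    for i in range(n_atoms):
        el = elements[int(rng.integers(len(elements)))]
        atom = Atom(f"{el}{i}", el, rng.uniform(0, box, 3),
                    occupancy=1.0, b_factor=float(rng.uniform(10, 40)))
        ch.residues.append(Residue("UNX", i + 1, "", "A", [atom]))
    return Structure(entry_id="rnd", chains=[ch])


@pytest.fixture
def random_structure_factory():
    return random_structure
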
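import numpy as np
import pytest

from structloc.structure import Atom, AtomicStructure
from structloc.synthetic import make_toy_structure


@pytest.fixture(scope="session")
def toy_structure() -> AtomicStructure:
    """3-helix poly-alanine toy domain (60 residues, 300 atoms)."""
    return make_toy_structure(n_helices=3, helix_length=20, seed=2)


@pytest.fixture(scope="session")
def small_structure() -> AtomicStructure:
    """Single short helix for fast map/docking tests."""
    return make_toy_structure(n_helices=1, helix_length=10, seed=0)


def single_atom(element="C", coord=(0.0, 0.0, 0.0), radius=1.7, serial=1):
    return AtomicStructure(atoms=[Atom(serial, element, radius, np.array(coord))])
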
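import numpy as np
import pytest

from cagecraft import core
from cagecraft.toyset import toy_block

METHANE_MOLBLOCK = """\

  toyset

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    0.6300    0.6300    0.6300 H   0  0
   -0.6300   -0.6300    0.6300 H   0  0
   -0.6300    0.6300   -0.6300 H   0  0
    0.6300   -0.6300   -0.6300 H   0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
"""


@pytest.fixture(scope="session")
def methane():
    return core.load_molecule(METHANE_MOLBLOCK, "mol")


@pytest.fixture(scope="session")
def diamine():
    return toy_block("diamine")


@pytest.fixture(scope="session")
def diamine_asym():
    return toy_block("diamine_asym")


@pytest.fixture(scope="session")
def dialdehyde():
    return toy_block("dialdehyde")


@pytest.fixture(scope="session")
def trialdehyde():
    return toy_block("trialdehyde")


@pytest.fixture(scope="session")
def triamine():
    return toy_block("triamine")


@pytest.fixture(scope="session")
def tetraaldehyde():
    return toy_block("tetraaldehyde")


@pytest.fixture(scope="session")
def hexaaldehyde():
    return toy_block("hexaaldehyde")


def toy_molecule(elements, coords, bonds=()):
    """Hand-built molecule for geometry unit tests."""
    atoms = [core.Atom(e) for e in elements]
    bond_objs = [core.Bond(a, b) for a, b in bonds]
    return core.Molecule(atoms, bond_objs, [np.asarray(coords, dtype=float)])


@pytest.fixture
def make_molecule():
    return toy_molecule
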
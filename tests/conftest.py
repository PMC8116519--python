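import numpy as np
import pytest

import mapent as me


@pytest.fixture(scope="session")
def toy_atoms():
    """~100-atom procedural chain used across the suite."""
    return me.make_toy_structure(25, seed=1)


@pytest.fixture(scope="session")
def toy_graph(toy_atoms):
    return me.build_graph(toy_atoms)


@pytest.fixture(scope="session")
def tiny_atoms():
    """10-atom structure whose N=3 mapping space has 120 elements."""
    return me.make_toy_structure(6, seed=3).take(range(10))


@pytest.fixture(scope="session")
def tiny_graph(tiny_atoms):
    return me.build_graph(tiny_atoms)


@pytest.fixture(scope="session")
def tiny_oracle(tiny_graph):
    return me.ToyOracle(tiny_graph)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.400   0.300   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       3.100   1.200   0.500  1.00  0.00           O
ATOM      5  H   GLY A   1       0.300   0.900   0.100  1.00  0.00           H
ATOM      6  HA2 GLY A   1       1.100  -0.800   0.600  1.00  0.00           H
ATOM      7  HA3 GLY A   1       1.200  -0.400  -0.900  1.00  0.00           H
ATOM      8  H2  GLY A   1      -0.500  -0.700   0.300  1.00  0.00           H
ATOM      9  H3  GLY A   1      -0.600   0.600  -0.300  1.00  0.00           H
END
"""


@pytest.fixture
def glycine_pdb_text():
    return GLY_PDB
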
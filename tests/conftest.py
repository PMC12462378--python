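import numpy as np
import pytest

from ppisite.residue_graph import build_graph
from ppisite.synthetic_data import SyntheticSpec, generate_protein

# a 3-residue chain A: ALA (2 side-chain-ish atoms beyond CB? use CB only),
# GLY (backbone only -> CA fallback), SER (CB + OG)
TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       3.000   0.000   0.000  1.00 10.00           O
ATOM      5  CB  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      6  N   GLY A   2       4.000   4.000   4.000  1.00 10.00           N
ATOM      7  CA  GLY A   2       5.000   5.000   5.000  1.00 10.00           C
ATOM      8  C   GLY A   2       6.000   5.000   5.000  1.00 10.00           C
ATOM      9  O   GLY A   2       7.000   5.000   5.000  1.00 10.00           O
ATOM     10  N   SER A   3       8.000   8.000   8.000  1.00 10.00           N
ATOM     11  CA  SER A   3       9.000   9.000   9.000  1.00 10.00           C
ATOM     12  C   SER A   3      10.000   9.000   9.000  1.00 10.00           C
ATOM     13  O   SER A   3      11.000   9.000   9.000  1.00 10.00           O
ATOM     14  CB  SER A   3       0.000   0.000   0.000  1.00 10.00           C
ATOM     15  OG  SER A   3       2.000   0.000   0.000  1.00 10.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(rng, n=12, d_node=8, cutoff=14.0, with_labels=True):
    """Small random labeled graph for model/loss tests."""
    coords = rng.uniform(0, 25, size=(n, 3))
    features = rng.random((n, d_node))
    labels = rng.integers(0, 2, size=n) if with_labels else None
    return build_graph(coords, features, labels=labels, name="rand", cutoff=cutoff)


@pytest.fixture
def small_graph(rng):
    return random_graph(rng)


@pytest.fixture
def synth_protein():
    spec = SyntheticSpec(n_proteins=1, length_range=(30, 40), seed=7)
    return generate_protein(35, spec, seed=99)
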
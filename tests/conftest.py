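import numpy as np
import pytest

from msmkin import synthetic


@pytest.fixture(scope="session")
def small_spec() -> synthetic.GroundTruthSpec:
    """Scaled-down generator spec for fast unit tests."""
    return synthetic.GroundTruthSpec(n_replicas=2, n_frames=1200, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return synthetic.simulate_trajectories(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


THREE_ATOM_PDB = """\
ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   GLY A   1       3.000   3.500   3.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   GLY A   1       3.000   3.500   3.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       1.100   2.100   3.100  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.600   2.100   3.100  1.00  0.00           C
ATOM      3  C   GLY A   1       3.100   3.600   3.100  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "two_model.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path
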
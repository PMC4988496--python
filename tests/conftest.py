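import numpy as np
import pytest

from mdflex import Structure, Trajectory, synthetic_stator


def make_structure(n_atoms=5, chain="A", seed=0, names=None):
    """Small random Cα-style structure for geometry tests."""
    rng = np.random.default_rng(seed)
    names = names or ["CA"] * n_atoms
    return Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(["C"] * n_atoms, dtype=object),
        chain_ids=np.array([chain] * n_atoms, dtype=object),
        res_ids=np.arange(1, n_atoms + 1),
        res_names=np.array(["ALA"] * n_atoms, dtype=object),
        masses=np.full(n_atoms, 12.011),
        coords=rng.uniform(-10, 10, size=(n_atoms, 3)),
    )


def make_trajectory(structure, frames, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(
        structure, frames, np.arange(frames.shape[0], dtype=float) * dt
    )


@pytest.fixture
def small_structure():
    return make_structure(5, seed=42)


@pytest.fixture(scope="session")
def stator():
    """Shared synthetic two-chain stator with planted Gaussian modes."""
    structure, traj = synthetic_stator(n_frames=300, seed=11)
    return structure, traj


@pytest.fixture(scope="session")
def stator_big():
    """High-sampling (5000-frame) stator ensemble for recovery checks."""
    structure, traj = synthetic_stator(n_frames=5000, seed=3)
    return structure, traj


TINY_PDB = """\
ATOM      1  N   GLY E   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY E   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA G   2       2.500   1.400   0.300  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   3       4.000   1.000   0.000  1.00  0.00           C
END
"""

ALTLOC_TIE_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.50  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p
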
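import math

import numpy as np
import pytest

from efmoscan.system_model import (Atom, MolecularSystem, detect_bonds,
                                   fragment_by_residue)

WATER_OH = 0.95
WATER_ANGLE = math.radians(104.52)

# handwritten two-residue peptide (GLY-GLY) plus one water
GLY_GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.132   2.752   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.598   2.520   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.028   1.362   0.000  1.00  0.00           O
HETATM    9  O   HOH A   3       0.500   4.500   1.000  1.00  0.00           O
HETATM   10  H1  HOH A   3       1.300   4.900   1.200  1.00  0.00           H
HETATM   11  H2  HOH A   3      -0.200   5.100   1.100  1.00  0.00           H
END
"""


def water_atoms(origin=np.zeros(3), rotation=np.eye(3), start_index=0,
                residue_id=0):
    local = np.array([
        [0.0, 0.0, 0.0],
        [WATER_OH, 0.0, 0.0],
        [WATER_OH * math.cos(WATER_ANGLE), WATER_OH * math.sin(WATER_ANGLE), 0.0],
    ])
    out = []
    for k, (el, pos) in enumerate(zip("OHH", local @ rotation.T + origin)):
        out.append(Atom(start_index + k, el, pos, residue_id=residue_id,
                        residue_name="HOH"))
    return out


def water_system(centers, seed=0):
    """Waters at given oxygen positions with seeded random orientations."""
    rng = np.random.default_rng(seed)
    atoms = []
    for w, c in enumerate(centers):
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        atoms.extend(water_atoms(np.asarray(c, float), q, 3 * w, w))
    system = MolecularSystem(atoms)
    detect_bonds(system)
    fragment_by_residue(system)
    return system


def random_rotation_matrix(rng):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def gly_gly_pdb(tmp_path):
    p = tmp_path / "glygly.pdb"
    p.write_text(GLY_GLY_PDB)
    return p


@pytest.fixture
def equilibrium_water():
    system = MolecularSystem(water_atoms())
    detect_bonds(system)
    fragment_by_residue(system)
    return system


@pytest.fixture
def water_pair_3A():
    return water_system([[0.0, 0.0, 0.0], [3.0, 0.3, 0.2]], seed=4)


@pytest.fixture
def five_waters():
    centers = [[0, 0, 0], [3.0, 0.3, 0.0], [0.5, 3.2, 0.4],
               [6.5, 1.0, 3.5], [2.8, 5.8, 2.0]]
    return water_system(centers, seed=3)
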
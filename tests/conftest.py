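import numpy as np
import pytest
from rdkit import Chem

from arscreen.chemio import Molecule, embed_conformer


def mol_from_smiles(smiles: str, mol_id: str = "m") -> Molecule:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, f"bad test SMILES {smiles!r}"
    return Molecule(m, mol_id)


@pytest.fixture(scope="session")
def make_mol():
    return mol_from_smiles


# small, chemically varied molecules (<= 12 heavy atoms) for oracle sweeps
ORACLE_SMILES = [
    "C", "CC", "CCC", "CCO", "CC(C)C", "c1ccccc1", "c1ccncc1",
    "CC(=O)O", "NCC(=O)O", "FC(F)F", "ClCCl", "CC(=O)NC",
    "c1ccoc1", "c1ccsc1", "OCC(O)CO", "N#Cc1ccccc1", "CCOC(C)=O",
    "Cc1ccc(N)cc1", "FC(F)(F)c1ccccc1", "c1cnc2ccnn2c1",
]


@pytest.fixture(scope="session")
def oracle_molecules():
    return [mol_from_smiles(s, f"orc{i}") for i, s in enumerate(ORACLE_SMILES)]


@pytest.fixture(scope="session")
def embedded_molecules(oracle_molecules):
    return [embed_conformer(m, seed=11) for m in oracle_molecules]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def rotate():
    return random_rotation
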
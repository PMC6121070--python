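"""Molecule and activity-table I/O, conformer embedding, graph distances.

All chemistry passes through RDKit.  A :class:`Molecule` wraps one sanitized
RDKit mol (largest covalent fragment of the input record) plus a stable id.
3D-dependent descriptors require a conformer produced by
:func:`embed_conformer`, which is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)


class MoleculeReadError(RuntimeError):
    """Input file unreadable or yielded zero valid molecules."""


class EmbeddingError(RuntimeError):
    """3D embedding failed for a molecule; callers exclude it downstream."""


class DisconnectedGraphError(ValueError):
    """Distance matrix requested on a disconnected graph."""


@dataclass(frozen=True)
class Molecule:
    """One screened compound: chemical graph plus optional 3D conformer.

    ``mol`` keeps hydrogens implicit until :func:`embed_conformer` adds
    explicit hydrogens along with coordinates.  Conventions: 2D descriptors
    use the hydrogen-depleted graph; GETAWAY/WHIM/geometrical descriptors use
    all atoms including hydrogens.
    """

    mol: Chem.Mol
    mol_id: str

    @property
    def heavy(self) -> Chem.Mol:
        """Hydrogen-depleted graph."""
        return Chem.RemoveHs(self.mol)

    @property
    def with_hs(self) -> Chem.Mol:
        """Graph with explicit hydrogens (coordinates preserved if present)."""
        if any(a.GetAtomicNum() == 1 for a in self.mol.GetAtoms()):
            return self.mol
        return Chem.AddHs(self.mol)

    @property
    def num_heavy_atoms(self) -> int:
        return self.heavy.GetNumAtoms()

    @property
    def has_coords(self) -> bool:
        return self.mol.GetNumConformers() > 0

    def coords(self) -> np.ndarray:
        """All-atom Cartesian coordinates in Angstrom (requires embedding)."""
        if not self.has_coords:
            raise ValueError(f"molecule {self.mol_id!r} has no conformer")
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def read_molecules(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read a SMILES (.smi, one record per line, optional name) or SDF file.

    Invalid records are skipped with a logged warning; multi-fragment records
    keep their largest covalent fragment.  Raises :class:`MoleculeReadError`
    if the file is unreadable or contains no valid record.
    """
    path = Path(path)
    if not path.exists():
        raise MoleculeReadError(f"no such file: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unknown format {fmt!r}")

    mols: list[Molecule] = []
    n_skipped = 0
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            raw = Chem.MolFromSmiles(parts[0])
            if raw is None:
                n_skipped += 1
                logger.warning("%s:%d: unparsable SMILES %r", path, lineno, parts[0])
                continue
            name = parts[1].strip() if len(parts) > 1 else f"mol_{lineno}"
            mols.append(Molecule(_largest_fragment(raw), name))
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, raw in enumerate(supplier):
            if raw is None:
                n_skipped += 1
                logger.warning("%s: record %d unparsable, skipped", path, i + 1)
                continue
            name = raw.GetProp("_Name") if raw.HasProp("_Name") and raw.GetProp("_Name") else f"mol_{i + 1}"
            mols.append(Molecule(_largest_fragment(raw), name))

    if not mols:
        raise MoleculeReadError(f"{path}: no valid molecule records (skipped {n_skipped})")
    if n_skipped:
        logger.warning("%s: skipped %d invalid record(s)", path, n_skipped)
    return mols


def write_smiles(mols: list[Molecule], path: str | Path) -> None:
    """Write canonical SMILES, one ``smiles id`` record per line."""
    Path(path).write_text("".join(f"{m.smiles()} {m.mol_id}\n" for m in mols))


def embed_conformer(molecule: Molecule, seed: int = 2018) -> Molecule:
    """Deterministic 3D embedding: ETKDG distance geometry + MMFF minimization.

    Hydrogens are made explicit (geometric descriptors include them).  The
    same (molecule, seed) pair always yields identical coordinates.  Raises
    :class:`EmbeddingError` on failure so callers can exclude the record.
    """
    molh = Chem.AddHs(Chem.Mol(molecule.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise EmbeddingError(f"3D embedding failed for molecule {molecule.mol_id!r}")
    try:
        AllChem.MMFFOptimizeMolecule(molh)
    except Exception as exc:  # MMFF typing can fail for exotic atoms
        logger.warning("MMFF minimization skipped for %s: %s", molecule.mol_id, exc)
    return replace(molecule, mol=molh)


def topological_distance_matrix(mol: Chem.Mol | Molecule, include_h: bool = False) -> np.ndarray:
    """Integer shortest-bond-path matrix.

    ``include_h=False`` (default) uses the hydrogen-depleted graph, the
    convention of the 2D descriptors; ``include_h=True`` uses all atoms, the
    convention of the leverage-autocorrelation (GETAWAY) lags.
    """
    if isinstance(mol, Molecule):
        mol = mol.with_hs if include_h else mol.heavy
    d = np.asarray(Chem.GetDistanceMatrix(mol))
    if np.isinf(d).any() or d.max() > 1e7:
        raise DisconnectedGraphError("graph is disconnected; take the largest fragment first")
    return d.astype(int)


# ---------------------------------------------------------------------------
# activity tables

@dataclass(frozen=True)
class ActivityRecord:
    """Compound activity: IC50 in molar units and pIC50 = -log10(IC50)."""

    compound_id: str
    ic50: float
    pic50: float = field(init=False)

    def __post_init__(self):
        if not self.ic50 > 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50}")
        object.__setattr__(self, "pic50", -math.log10(self.ic50))


def pic50_from_ic50(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 / M); 10 uM -> 5.0."""
    if not ic50_molar > 0:
        raise ValueError("IC50 must be positive")
    return -math.log10(ic50_molar)


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV with header ``id,ic50_molar`` or ``id,pic50``.

    Returns a DataFrame with columns ``id`` and ``pic50``.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"id", "pic50"} <= cols:
        out = df[["id", "pic50"]].copy()
    elif {"id", "ic50_molar"} <= cols:
        out = pd.DataFrame({
            "id": df["id"],
            "pic50": [pic50_from_ic50(v) for v in df["ic50_molar"]],
        })
    else:
        raise ValueError(f"{path}: expected header id,ic50_molar or id,pic50; got {sorted(cols)}")
    out["id"] = out["id"].astype(str)
    return out
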
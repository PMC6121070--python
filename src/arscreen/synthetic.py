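"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all seed-deterministic:

* :func:`gen_library` — a SMILES screening library assembled from a curated
  fragment grammar, with controlled fractions of scaffold-containing
  molecules and of molecules violating exactly one Lipinski rule, plus a
  truth table recording every planted property (and, optionally, the
  model predictions, so downstream stage counts are predictable exactly);
* :func:`gen_qsar_dataset` — descriptor/activity matrices with a known
  sparse linear relationship plus Gaussian noise at the RMSE scale the
  published models report (about 0.3 pIC50 units);
* :func:`gen_trajectory` — coordinate time series with one donor-H-acceptor
  triplet planted at a known H-bond occupancy, geometry margins 0.5 A beyond
  the cutoffs so boolean outcomes are robust to floating-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from . import descriptors as desc_mod
from . import qsar
from .chemio import Molecule
from .screening import PYRAZOLOPYRIMIDINE_SMARTS, lipinski_filter
from .topo import lipinski_properties
from .traj import Trajectory


@dataclass(frozen=True)
class QSARSimSpec:
    """Sparse-linear simulation: p_true signal columns among p_total."""

    n_train: int = 60
    n_ext: int = 20
    p_total: int = 53
    p_true: int = 3
    coef_low: float = 1.0
    coef_high: float = 2.0
    intercept: float = 7.0
    noise_sigma: float = 0.3

    def __post_init__(self):
        if self.p_true > self.p_total:
            raise ValueError("p_true must not exceed p_total")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass(frozen=True)
class TrajectorySimSpec:
    frames: int = 200
    occupancy: float = 0.35
    noise_sigma: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for all three generators."""

    seed: int = 0
    library_size: int = 200
    scaffold_fraction: float = 0.2
    lipinski_violation_fraction: float = 0.2
    qsar: QSARSimSpec = field(default_factory=QSARSimSpec)
    trajectory: TrajectorySimSpec = field(default_factory=TrajectorySimSpec)

    def __post_init__(self):
        for f in (self.scaffold_fraction, self.lipinski_violation_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.scaffold_fraction + self.lipinski_violation_fraction > 1.0:
            raise ValueError("scaffold and violator fractions sum above 1")


# ---------------------------------------------------------------------------
# molecule library

_SCAFFOLD_CORE = PYRAZOLOPYRIMIDINE_SMARTS          # pyrazolo[1,5-a]pyrimidine
_SCAFFOLD_PATT = Chem.MolFromSmarts(_SCAFFOLD_CORE)

# substituents written as SMILES prefixes whose last atom bonds to the core
_SUBSTITUENTS = (
    "C", "CC", "CCC", "CC(C)", "CO", "CCO", "CN", "CN(C)",
    "Cl", "F", "Br", "N#C", "CS", "FC(F)(F)", "CC(=O)N", "COC",
    "c1ccccc1", "Cc1ccccc1", "COc1ccccc1",
)

# bulkier, chemically heterogeneous substituents: raise the information-content
# and R-autocorrelation descriptors so part of the scaffold series clears the
# four-model consensus, as a real hit series would
_BULKY_SUBSTITUENTS = (
    "CC(=O)Nc1ccccc1", "COc1ccc(C(=O)N)cc1", "CC(C)NC(=O)",
    "FC(F)(F)c1ccc(CN)cc1", "CN(C)CCO", "OCC(O)Nc1ccccc1",
    "CSc1ccc(CNC(C)=O)cc1", "ClCc1ccc(OC)cc1", "NC(=O)CS", "CC(O)CN(C)",
)

_DECOY_CORES = (
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1",
    "c1ccc2ccccc2c1", "c1ccoc1", "c1ccsc1", "c1ccc2ncccc2c1",
)

# one-rule Lipinski violators; chain/ring sizes varied per draw
_HBD_VIOLATORS = (
    "OCC(O)C(O)C(O)CO",                # xylitol: 5 donors
    "OC1C(O)C(O)C(O)C(O)C1O",          # inositol: 6 donors
    "OCC(O)C(O)C(O)C(O)CO",            # sorbitol: 6 donors
)
_MW_VIOLATORS = (
    "CC(=O)Nc1c(I)c(NC(C)=O)c(I)c(C(=O)O)c1I",        # triiodinated benzamide acid
    "CCC(=O)Nc1c(I)c(NC(C)=O)c(I)c(C(=O)O)c1I",
    "CC(=O)Nc1c(I)c(NC(C)=O)c(I)c(C(=O)OC)c1I",
)


def _peg_smiles(n_oxygens: int) -> str:
    """CH3-O-(CH2CH2-O)k-CH3 with the requested oxygen count (>= 10 violates HBA)."""
    return "CO" + "CCO" * (n_oxygens - 1) + "C"


def _alkylbenzene(n_carbons: int) -> str:
    return "C" * n_carbons + "c1ccccc1"


def _checked(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def _violator_pool() -> list[tuple[str, str]]:
    """(smiles, violated rule) pairs, each violating exactly that one rule."""
    pool = [(s, "HBD") for s in _HBD_VIOLATORS]
    pool += [(s, "MW") for s in _MW_VIOLATORS]
    pool += [(_peg_smiles(k), "HBA") for k in (10, 11)]
    pool += [(_alkylbenzene(k), "AlogP") for k in (10, 11, 12, 13)]
    return pool


def gen_library(spec: SyntheticSpec, with_predictions: bool = True,
                models: list[qsar.LinearModel] | None = None,
                threshold: float = 7.0,
                ) -> tuple[list[Molecule], pd.DataFrame]:
    """Generate a screening library plus its ground-truth table.

    The truth table records, per molecule: planted category, scaffold
    presence, Lipinski outcome with the single violated rule, and — when
    ``with_predictions`` — whether all model descriptors are computable and
    whether the molecule clears the consensus threshold.  Those columns make
    every cascade stage count predictable exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_scaffold = round(spec.scaffold_fraction * spec.library_size)
    n_viol = round(spec.lipinski_violation_fraction * spec.library_size)
    if n_scaffold + n_viol > spec.library_size:
        raise ValueError("planted fractions exceed library size")
    n_decoy = spec.library_size - n_scaffold - n_viol

    entries: list[tuple[str, str, str]] = []   # (smiles, category, violated_rule)

    scaffold_subs = _SUBSTITUENTS + _BULKY_SUBSTITUENTS * 2
    made = 0
    while made < n_scaffold:
        sub = scaffold_subs[rng.integers(0, len(scaffold_subs))]
        smi = _SCAFFOLD_CORE if rng.random() < 0.1 else sub + _SCAFFOLD_CORE
        mol = _checked(smi)
        if mol is None or not mol.HasSubstructMatch(_SCAFFOLD_PATT):
            continue
        props = lipinski_properties(Molecule(mol, "tmp"))
        if not (props.hbd < 5 and props.hba < 10 and props.mw < 500 and props.alogp < 5):
            continue
        entries.append((smi, "scaffold", ""))
        made += 1

    pool = _violator_pool()
    made = 0
    while made < n_viol:
        smi, rule = pool[rng.integers(0, len(pool))]
        mol = _checked(smi)
        assert mol is not None and not mol.HasSubstructMatch(_SCAFFOLD_PATT)
        props = lipinski_properties(Molecule(mol, "tmp"))
        violated = [name for name, ok in (
            ("HBD", props.hbd < 5), ("HBA", props.hba < 10),
            ("MW", props.mw < 500), ("AlogP", props.alogp < 5)) if not ok]
        assert violated == [rule], f"{smi} violates {violated}, planned [{rule}]"
        entries.append((smi, "violator", rule))
        made += 1

    made = 0
    while made < n_decoy:
        core = _DECOY_CORES[rng.integers(0, len(_DECOY_CORES))]
        sub = _SUBSTITUENTS[rng.integers(0, len(_SUBSTITUENTS))]
        smi = core if rng.random() < 0.15 else sub + core
        mol = _checked(smi)
        if mol is None or mol.HasSubstructMatch(_SCAFFOLD_PATT):
            continue
        props = lipinski_properties(Molecule(mol, "tmp"))
        if not (props.hbd < 5 and props.hba < 10 and props.mw < 500 and props.alogp < 5):
            continue
        entries.append((smi, "decoy", ""))
        made += 1

    order = rng.permutation(len(entries))
    mols, rows = [], []
    for new_idx, old_idx in enumerate(order):
        smi, category, rule = entries[old_idx]
        mid = f"SYN{new_idx:05d}"
        mol = Molecule(_checked(smi), mid)
        mols.append(mol)
        rows.append({
            "id": mid, "smiles": smi, "category": category,
            "has_scaffold": category == "scaffold",
            "lipinski_pass": category != "violator",
            "violated_rule": rule,
        })
    truth = pd.DataFrame(rows).set_index("id")

    if with_predictions:
        models = models if models is not None else qsar.published_models()
        needed = sorted({d for m in models for d in m.descriptor_ids})
        passing = [m for m in mols if truth.loc[m.mol_id, "lipinski_pass"]]
        values, _ = desc_mod.compute_matrix(passing, needed, seed=spec.seed)
        preds = pd.DataFrame({m.name: qsar.predict_frame(m, values) for m in models})
        truth["descriptors_ok"] = False
        truth["consensus_pass"] = False
        for mid in preds.index:
            row = preds.loc[mid]
            truth.loc[mid, "descriptors_ok"] = bool(row.notna().all())
            truth.loc[mid, "consensus_pass"] = bool(row.notna().all() and (row > threshold).all())

    return mols, truth


def write_library(mols: list[Molecule], path: str | Path) -> None:
    Path(path).write_text("".join(f"{m.smiles()} {m.mol_id}\n" for m in mols))


# ---------------------------------------------------------------------------
# QSAR simulation

@dataclass(frozen=True)
class QSARDataset:
    x_train: pd.DataFrame
    y_train: np.ndarray
    x_ext: pd.DataFrame
    y_ext: np.ndarray
    true_model: qsar.LinearModel
    true_columns: tuple[str, ...]


def gen_qsar_dataset(spec: SyntheticSpec) -> QSARDataset:
    """Descriptor/activity matrices with a planted sparse linear signal.

    Columns are i.i.d. standard normal; the response adds Gaussian noise of
    scale ``qsar.noise_sigma`` to a linear combination of ``p_true`` randomly
    placed columns whose coefficients have magnitude in
    [coef_low, coef_high] and random sign.
    """
    q = spec.qsar
    rng = np.random.default_rng(spec.seed)
    n = q.n_train + q.n_ext
    x = rng.standard_normal((n, q.p_total))
    cols = [f"d{i:03d}" for i in range(q.p_total)]
    true_idx = np.sort(rng.choice(q.p_total, size=q.p_true, replace=False))
    coefs = rng.uniform(q.coef_low, q.coef_high, size=q.p_true)
    coefs *= rng.choice([-1.0, 1.0], size=q.p_true)
    y = q.intercept + x[:, true_idx] @ coefs + rng.normal(0.0, q.noise_sigma, size=n)

    xdf = pd.DataFrame(x, columns=cols)
    true_cols = tuple(cols[i] for i in true_idx)
    model = qsar.LinearModel("true", true_cols, tuple(coefs), q.intercept)
    return QSARDataset(
        x_train=xdf.iloc[: q.n_train].reset_index(drop=True),
        y_train=y[: q.n_train],
        x_ext=xdf.iloc[q.n_train:].reset_index(drop=True),
        y_ext=y[q.n_train:],
        true_model=model,
        true_columns=true_cols,
    )


# ---------------------------------------------------------------------------
# trajectory simulation

#: planted geometry (Angstrom): bonded N-H, near-linear H-bond when present
_D_H = 1.0
_DA_PRESENT = 2.9       # < 3.5 cutoff with margin
_DA_ABSENT = 4.2        # >= 0.5 A beyond the 3.5 cutoff


def gen_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, float, tuple[int, int, int]]:
    """Planted-occupancy trajectory with one donor-H-acceptor triplet.

    Exactly ``round(occupancy * frames)`` frames satisfy the default H-bond
    criterion; the rest violate the distance cutoff by at least 0.5 A.
    Returns the trajectory, the constructed occupancy fraction and the
    (donor, hydrogen, acceptor) atom indices.
    """
    t = spec.trajectory
    rng = np.random.default_rng(spec.seed + 1)
    n_on = round(t.occupancy * t.frames)
    on = np.zeros(t.frames, dtype=bool)
    on[rng.permutation(t.frames)[:n_on]] = True

    frames = np.empty((t.frames, 3, 3))
    for i in range(t.frames):
        jitter = rng.normal(0.0, t.noise_sigma, size=(3, 3))
        da = _DA_PRESENT if on[i] else _DA_ABSENT
        base = np.array([
            [0.0, 0.0, 0.0],        # donor N
            [_D_H, 0.0, 0.0],       # hydrogen on the donor
            [da, 0.0, 0.0],         # acceptor O
        ])
        frames[i] = base + jitter
    traj = Trajectory(frames, names=("N", "H", "O"), resids=(1, 1, 2),
                      resnames=("DON", "DON", "ACC"))
    return traj, n_on / t.frames, (0, 1, 2)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL per frame) readable by MDAnalysis."""
    names = traj.names or tuple(f"X{i}" for i in range(traj.n_atoms))
    resids = traj.resids or (1,) * traj.n_atoms
    resnames = traj.resnames or ("UNK",) * traj.n_atoms
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for a in range(traj.n_atoms):
            x, y, z = traj.coords[f, a]
            element = names[a][0]
            lines.append(
                f"ATOM  {a + 1:5d} {names[a]:<4s}{resnames[a]:>3s} A{resids[a]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
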
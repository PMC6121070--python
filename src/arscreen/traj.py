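"""Trajectory post-analysis: H-bond occupancy, RMSD, frame extraction,
cluster representatives.

Works on lightweight in-memory trajectories (frames x atoms x 3, Angstrom)
loaded from multi-model PDB or XYZ files via MDAnalysis.  A hydrogen bond in
a frame requires donor-acceptor distance below the cutoff (default 3.5 A)
and a donor-H...acceptor angle, measured at the hydrogen, above the cutoff
(default 120 deg).  Occupancy is the fraction of frames where both hold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.analysis.rms import rmsd as _mda_rmsd


@dataclass(frozen=True)
class Trajectory:
    """Coordinate time series with per-atom labels."""

    coords: np.ndarray                  # (F, A, 3) Angstrom
    names: tuple[str, ...] = ()
    resids: tuple[int, ...] = ()
    resnames: tuple[str, ...] = ()

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3 or c.shape[0] < 1:
            raise ValueError("coords must have shape (frames >= 1, atoms, 3)")
        object.__setattr__(self, "coords", c)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def load_trajectory(path: str | Path) -> Trajectory:
    """Load a multi-model PDB or XYZ file."""
    u = mda.Universe(str(path))
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    names = tuple(u.atoms.names) if hasattr(u.atoms, "names") else ()
    try:
        resids = tuple(int(r) for r in u.atoms.resids)
        resnames = tuple(u.atoms.resnames)
    except mda.exceptions.NoDataError:
        resids, resnames = (), ()
    return Trajectory(frames, names, resids, resnames)


def extract_frames(traj: Trajectory, start_index: int, end_index: int, count: int) -> Trajectory:
    """Evenly spaced frame subset over [start, end], endpoints included.

    Mirrors the snapshot-extraction step of production-run post-analysis
    (e.g. 2,000 even snapshots over the last fifth of a run).
    """
    if not (0 <= start_index <= end_index < traj.n_frames):
        raise IndexError(f"window [{start_index}, {end_index}] outside 0..{traj.n_frames - 1}")
    avail = end_index - start_index + 1
    if count < 1 or count > avail:
        raise ValueError(f"count {count} not in 1..{avail}")
    if count == 1:
        idx = np.array([start_index])
    else:
        idx = np.rint(np.linspace(start_index, end_index, count)).astype(int)
    return Trajectory(traj.coords[idx], traj.names, traj.resids, traj.resnames)


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond definition: D-A distance and D-H...A angle cutoffs."""

    max_distance: float = 3.5      # Angstrom (0.35 nm)
    min_angle: float = 120.0       # degrees, vertex at the hydrogen

    def __post_init__(self):
        if not self.max_distance > 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass(frozen=True)
class HBondStat:
    """Per-triplet occupancy and geometry averages.

    ``mean_distance``/``mean_angle`` average over occupied frames only;
    the ``_all`` variants average over every frame.
    """

    donor: int
    hydrogen: int
    acceptor: int
    occupancy: float
    mean_distance: float
    mean_angle: float
    mean_distance_all: float
    mean_angle_all: float


def _angles_at_hydrogen(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    v1 = d - h
    v2 = a - h
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_occupancy(traj: Trajectory, triplets: list[tuple[int, int, int]],
                    crit: HBondCriterion = HBondCriterion()) -> list[HBondStat]:
    """Occupancy statistics for donor-H-acceptor triplets (0-based indices)."""
    stats = []
    for don, hyd, acc in triplets:
        for idx, label in ((don, "donor"), (hyd, "hydrogen"), (acc, "acceptor")):
            if not 0 <= idx < traj.n_atoms:
                raise IndexError(f"{label} atom index {idx} out of range")
        if traj.names and not traj.names[hyd].upper().startswith("H"):
            raise ValueError(f"triplet hydrogen index {hyd} is atom {traj.names[hyd]!r}, not a hydrogen")
        dpos = traj.coords[:, don]
        hpos = traj.coords[:, hyd]
        apos = traj.coords[:, acc]
        dist = np.linalg.norm(dpos - apos, axis=1)
        ang = _angles_at_hydrogen(dpos, hpos, apos)
        present = (dist < crit.max_distance) & (ang > crit.min_angle)
        n_on = int(present.sum())
        stats.append(HBondStat(
            donor=don, hydrogen=hyd, acceptor=acc,
            occupancy=n_on / traj.n_frames,
            mean_distance=float(dist[present].mean()) if n_on else float("nan"),
            mean_angle=float(ang[present].mean()) if n_on else float("nan"),
            mean_distance_all=float(dist.mean()),
            mean_angle_all=float(ang.mean()),
        ))
    return stats


def hbond_table(stats: list[HBondStat], traj: Trajectory | None = None) -> pd.DataFrame:
    """Tabulate H-bond statistics with occupancy as a percentage."""
    rows = []
    for s in stats:
        label = lambda i: (traj.names[i] if traj and traj.names else str(i))
        rows.append({
            "Donor": label(s.donor), "Hydrogen": label(s.hydrogen),
            "Acceptor": label(s.acceptor),
            "Distance(A)": s.mean_distance, "Angle(deg)": s.mean_angle,
            "Occupancy (%)": 100.0 * s.occupancy,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RMSD

def backbone_rmsd(traj: Trajectory, reference_frame: int = 0,
                  selection: np.ndarray | list[int] | None = None) -> np.ndarray:
    """Per-frame RMSD (A) to a reference frame after optimal superposition.

    Each frame is translated and rotated (Kabsch) onto the reference before
    the RMSD is taken over the selected atoms (default: all atoms).
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    if sel.max() >= traj.n_atoms or sel.min() < 0:
        raise ValueError("selection index out of range")
    ref = traj.coords[reference_frame][sel]
    return np.array([
        _mda_rmsd(frame[sel], ref, center=True, superposition=True)
        for frame in traj.coords
    ])


def pairwise_rmsd_matrix(traj: Trajectory, selection=None) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between all frame pairs."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    f = traj.n_frames
    out = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            out[i, j] = out[j, i] = _mda_rmsd(
                traj.coords[i][sel], traj.coords[j][sel], center=True, superposition=True)
    return out


# ---------------------------------------------------------------------------
# clustering

def cluster_representative(traj: Trajectory, k: int, seed: int = 0,
                           selection=None) -> tuple[np.ndarray, list[int], float]:
    """Seeded k-medoids clustering on the pairwise superposed-RMSD matrix.

    Returns ``(labels, representative frame index per cluster,
    largest-cluster fraction)``.  The representative of a cluster is its
    medoid — the member with the lowest summed RMSD to the cluster, hence
    lowest RMSD to the cluster center.  Deterministic for a fixed seed.
    """
    if not 1 <= k <= traj.n_frames:
        raise ValueError(f"k must lie in 1..{traj.n_frames}")
    d = pairwise_rmsd_matrix(traj, selection)
    f = traj.n_frames
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(f, size=k, replace=False))

    for _ in range(200):
        labels = np.argmin(d[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster with the point farthest from its medoid
                far = int(np.argmax(np.min(d[:, new_medoids], axis=1)))
                new_medoids[c] = far
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]  # ties -> lowest index
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids

    labels = np.argmin(d[:, medoids], axis=1)
    sizes = np.bincount(labels, minlength=k)
    return labels, [int(m) for m in medoids], float(sizes.max() / f)
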
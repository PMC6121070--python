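"""Registry mapping published descriptor IDs to compute functions.

The four scoring equations consume 19 named descriptors.  Each registry
entry takes an embedded :class:`~arscreen.chemio.Molecule` and returns a
:class:`~arscreen.topo.DescriptorValue`; 3D entries share one influence
matrix per molecule for efficiency.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import geom, topo
from .chemio import EmbeddingError, Molecule, embed_conformer
from .topo import DescriptorValue

logger = logging.getLogger(__name__)

_2D = {
    "GATS7v": lambda mol: topo.geary_autocorrelation(mol, 7, "v"),
    "GATS5e": lambda mol: topo.geary_autocorrelation(mol, 5, "e"),
    "BEHp7": lambda mol: topo.burden_eigenvalue(mol, 7, "p"),
    "IC1": lambda mol: topo.information_content(mol, 1),
    "IC5": lambda mol: topo.information_content(mol, 5),
    "IVDE": topo.vertex_degree_information,
    "C-009": topo.atom_centered_fragment_C009,
    "F05[N-F]": lambda mol: topo.pair_frequency(mol, "N", "F", 5),
    "BLTF96": topo.bltf96,
    "Depressant-80": topo.gvw_druglike_index,
}

_3D = {
    "E2u": lambda mol, im: geom.whim_e(mol, 2, "u"),
    "HATS3u": lambda mol, im: geom.getaway_hats(mol, 3, "u", im=im),
    "HATS4u": lambda mol, im: geom.getaway_hats(mol, 4, "u", im=im),
    "HATS7m": lambda mol, im: geom.getaway_hats(mol, 7, "m", im=im),
    "H6m": lambda mol, im: geom.getaway_h(mol, 6, "m", im=im),
    "R4u": lambda mol, im: geom.getaway_r(mol, 4, "u", maximal=False, im=im),
    "R6u+": lambda mol, im: geom.getaway_r(mol, 6, "u", maximal=True, im=im),
    "R8u+": lambda mol, im: geom.getaway_r(mol, 8, "u", maximal=True, im=im),
    "DISPp": lambda mol, im: geom.dispp(mol),
}

#: every descriptor ID the published equations use
ALL_DESCRIPTOR_IDS: tuple[str, ...] = tuple(_2D) + tuple(_3D)


def compute_descriptors(molecule: Molecule, ids: list[str] | None = None,
                        seed: int = 2018) -> dict[str, DescriptorValue]:
    """Compute named descriptors for one molecule.

    The molecule is embedded on demand when a 3D descriptor is requested;
    an embedding failure marks every 3D entry missing rather than raising.
    """
    ids = list(ids) if ids is not None else list(ALL_DESCRIPTOR_IDS)
    unknown = [i for i in ids if i not in _2D and i not in _3D]
    if unknown:
        raise KeyError(f"unknown descriptor id(s): {unknown}")

    out: dict[str, DescriptorValue] = {}
    for did in ids:
        if did in _2D:
            out[did] = _2D[did](molecule)

    need_3d = [i for i in ids if i in _3D]
    if need_3d:
        try:
            embedded = molecule if molecule.has_coords else embed_conformer(molecule, seed)
            im = geom.influence_matrix(embedded)
        except EmbeddingError as exc:
            logger.warning("%s", exc)
            for did in need_3d:
                out[did] = DescriptorValue.missing("embedding-failed")
        else:
            for did in need_3d:
                out[did] = _3D[did](embedded, im)
    return {did: out[did] for did in ids}


def compute_matrix(molecules: list[Molecule], ids: list[str] | None = None,
                   seed: int = 2018) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor matrix for a molecule list.

    Returns ``(values, reasons)``: values indexed by molecule id with NaN
    where a descriptor is undefined, and a same-shaped frame of reason codes
    (empty string where computed) — the sidecar written next to CSV output.
    """
    ids = list(ids) if ids is not None else list(ALL_DESCRIPTOR_IDS)
    values, reasons = {}, {}
    for mol in molecules:
        d = compute_descriptors(mol, ids, seed=seed)
        values[mol.mol_id] = {k: v.value for k, v in d.items()}
        reasons[mol.mol_id] = {k: (v.reason or "") for k, v in d.items()}
    vdf = pd.DataFrame.from_dict(values, orient="index")[ids]
    rdf = pd.DataFrame.from_dict(reasons, orient="index")[ids]
    return vdf, rdf


def write_matrix(values: pd.DataFrame, reasons: pd.DataFrame, path) -> None:
    """Write the descriptor matrix CSV plus a ``<path>.reasons.csv`` sidecar."""
    values.to_csv(path, index_label="id")
    nonempty = reasons[(reasons != "").any(axis=1)]
    nonempty.to_csv(str(path) + ".reasons.csv", index_label="id")
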
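"""Geometry-based (3D) molecular descriptors.

Covers the GETAWAY family (leverage autocorrelations HATS, H and R/R+), the
WHIM directional accessibility index E, and the displacement descriptor
DISPp (distance between the geometric and the polarizability-weighted
centroid).  All operate on the hydrogen-explicit conformer produced by
:func:`arscreen.chemio.embed_conformer`.

The central object is the molecular influence matrix
``H = M (M^T M)^{-1} M^T`` of the centered coordinate matrix M: a projection
onto the 3-dimensional column space of M, whose diagonal elements (atomic
leverages) measure how much each atom determines the molecular shape.  The
trace of a rank-3 projection is 3, which every fixture asserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .chemio import Molecule, topological_distance_matrix
from .properties import atom_weights
from .topo import DescriptorValue

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InfluenceMatrix:
    """Leverages, off-diagonal influence terms and geometric distances."""

    h: np.ndarray            # full A x A influence matrix
    r: np.ndarray            # A x A Euclidean distances (Angstrom)
    topo_d: np.ndarray       # A x A topological distances (H-explicit graph)

    @property
    def leverages(self) -> np.ndarray:
        return np.diag(self.h)


def influence_matrix(molecule: Molecule) -> InfluenceMatrix:
    """Molecular influence matrix of the centered all-atom conformer."""
    m = molecule.coords()
    m = m - m.mean(axis=0)
    # H = U U^T over the nonzero singular directions: numerically exact
    # projection (trace = rank to machine precision), degrades gracefully to
    # the pseudo-inverse behaviour for rank-deficient (linear/planar) geometry
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    nz = s > 1e-10 * s[0]
    if nz.sum() < 3:
        logger.info("rank-deficient coordinates for %s (rank %d)", molecule.mol_id, nz.sum())
    u = u[:, nz]
    h = u @ u.T
    r = squareform(pdist(m))
    return InfluenceMatrix(h=h, r=r, topo_d=topological_distance_matrix(molecule, include_h=True))


def _pair_mask(im: InfluenceMatrix, lag: int) -> np.ndarray | None:
    """Boolean upper-triangle mask of atom pairs at topological distance lag."""
    mask = np.triu(im.topo_d == lag, k=1)
    return mask if mask.any() else None


def getaway_hats(molecule: Molecule, lag: int, weight: str = "u",
                 im: InfluenceMatrix | None = None) -> DescriptorValue:
    """HATS_k(w) = sum over unordered pairs at lag k of (w_i h_i)(w_j h_j)."""
    im = im or influence_matrix(molecule)
    mask = _pair_mask(im, lag)
    if mask is None:
        return DescriptorValue.missing("no-pairs-at-lag")
    wh = atom_weights(molecule.with_hs, weight) * im.leverages
    return DescriptorValue.of(float(np.outer(wh, wh)[mask].sum()))


def getaway_h(molecule: Molecule, lag: int, weight: str = "m",
              im: InfluenceMatrix | None = None) -> DescriptorValue:
    """H_k(w): sum of positive off-diagonal influence terms h_ij w_i w_j."""
    im = im or influence_matrix(molecule)
    mask = _pair_mask(im, lag)
    if mask is None:
        return DescriptorValue.missing("no-pairs-at-lag")
    w = atom_weights(molecule.with_hs, weight)
    terms = im.h * np.outer(w, w)
    return DescriptorValue.of(float(terms[mask & (im.h > 0)].sum()))


def getaway_r(molecule: Molecule, lag: int, weight: str = "u", maximal: bool = False,
              im: InfluenceMatrix | None = None) -> DescriptorValue:
    """R_k(w) = sum_{i<j, d=k} sqrt(h_i h_j)/r_ij w_i w_j; R_k+ is the max term."""
    im = im or influence_matrix(molecule)
    mask = _pair_mask(im, lag)
    if mask is None:
        return DescriptorValue.missing("no-pairs-at-lag")
    lev = np.clip(im.leverages, 0.0, None)
    w = atom_weights(molecule.with_hs, weight)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.sqrt(np.outer(lev, lev)) / im.r * np.outer(w, w)
    vals = terms[mask]
    return DescriptorValue.of(float(vals.max() if maximal else vals.sum()))


def whim_e(molecule: Molecule, component: int, weight: str = "u") -> DescriptorValue:
    """WHIM directional accessibility E_m = (lambda_m^2 A) / sum_i s_im^4.

    lambda_m are eigenvalues of the (weighted) covariance of the centered
    coordinates, s_im the atom scores along principal axis m (m = 1..3,
    ordered by decreasing lambda).  An inverse-kurtosis measure: large when
    atoms spread evenly along the axis.
    """
    if component not in (1, 2, 3):
        raise ValueError("component must be 1, 2 or 3")
    m = molecule.coords()
    w = atom_weights(molecule.with_hs, weight)
    wsum = w.sum()
    center = (w[:, None] * m).sum(axis=0) / wsum
    mc = m - center
    cov = (mc * w[:, None]).T @ mc / wsum
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam_m = lam[component - 1]
    if lam_m < 1e-10:
        return DescriptorValue.missing("degenerate-axis")
    scores = mc @ vec[:, component - 1]
    a = m.shape[0]
    return DescriptorValue.of(float(lam_m ** 2 * a / np.sum(scores ** 4)))


def dispp(molecule: Molecule) -> DescriptorValue:
    """DISPp: distance (Angstrom) between the unweighted geometric centroid
    and the polarizability-weighted centroid of the conformer."""
    m = molecule.coords()
    w = atom_weights(molecule.with_hs, "p")
    geo = m.mean(axis=0)
    weighted = (w[:, None] * m).sum(axis=0) / w.sum()
    return DescriptorValue.of(float(np.linalg.norm(geo - weighted)))
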
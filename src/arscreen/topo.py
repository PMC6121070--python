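"""Graph-based (2D) molecular descriptors.

Implements the topological descriptors entering the published scoring
equations: Geary autocorrelations (GATS), Burden-matrix eigenvalues (BEH),
neighborhood-symmetry information content (IC), vertex-degree-equality
information (IVDE), the C-009 atom-centered fragment count, element-pair
frequencies at fixed topological distance (F05[N-F]), Moriguchi logP and the
Verhaar fish baseline-toxicity value derived from it (BLTF96), the
Ghose-Viswanadhan-Wendoloski antidepressant-likeness indicator
(Depressant-80), and the four Lipinski rule-of-five properties.

Conventions (documented in the methods note): 2D autocorrelations, Burden
matrices, IVDE and pair frequencies operate on the hydrogen-depleted graph;
information-content indices type atoms on the hydrogen-explicit graph.
Aromatic bonds carry conventional order 1.5 wherever bond order enters a
formula.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .chemio import Molecule, topological_distance_matrix
from .properties import atom_weights

__all__ = [
    "DescriptorValue",
    "geary_autocorrelation",
    "burden_eigenvalue",
    "information_content",
    "vertex_degree_information",
    "atom_centered_fragment_C009",
    "pair_frequency",
    "mlogp",
    "mlogp_terms",
    "bltf96",
    "gvw_druglike_index",
    "lipinski_properties",
]


@dataclass(frozen=True)
class DescriptorValue:
    """One descriptor result; undefined values carry a reason, never NaN."""

    value: float | None
    reason: str | None = None

    @property
    def computed(self) -> bool:
        return self.value is not None

    @staticmethod
    def of(value: float) -> "DescriptorValue":
        return DescriptorValue(float(value))

    @staticmethod
    def missing(reason: str) -> "DescriptorValue":
        return DescriptorValue(None, reason)


# ---------------------------------------------------------------------------
# autocorrelations

def geary_autocorrelation(molecule: Molecule, lag: int, weight: str) -> DescriptorValue:
    """Geary spatial autocorrelation GATS_k on the H-depleted graph.

    GATS_k = [sum_{d_ij=k} (w_i - w_j)^2 / (2 Delta_k)] /
             [sum_i (w_i - wbar)^2 / (A - 1)]

    with Delta_k the number of *ordered* atom pairs at topological distance k
    and w the carbon-scaled atomic property (schemes u, m, v, e, p).
    """
    heavy = molecule.heavy
    a = heavy.GetNumAtoms()
    if a < 2:
        return DescriptorValue.missing("too-few-atoms")
    w = atom_weights(heavy, weight)
    d = topological_distance_matrix(heavy)
    mask = d == lag
    delta_k = int(mask.sum())  # ordered pairs: symmetric mask counts both (i,j), (j,i)
    if delta_k == 0:
        return DescriptorValue.missing("no-pairs-at-lag")
    var = float(np.sum((w - w.mean()) ** 2)) / (a - 1)
    if var == 0.0:
        return DescriptorValue.missing("zero-variance")
    diff2 = (w[:, None] - w[None, :]) ** 2
    num = float(diff2[mask].sum()) / (2 * delta_k)
    return DescriptorValue.of(num / var)


# ---------------------------------------------------------------------------
# Burden eigenvalues

def burden_matrix(molecule: Molecule, weight: str) -> np.ndarray:
    """Burden connectivity matrix on the H-depleted graph.

    Diagonal: carbon-scaled atomic property.  Bonded pairs: 0.1 x
    conventional bond order (aromatic = 1.5), plus 0.01 when the bond touches
    a terminal (degree-1) atom.  Non-bonded pairs: 0.001.
    """
    heavy = molecule.heavy
    a = heavy.GetNumAtoms()
    b = np.full((a, a), 0.001)
    np.fill_diagonal(b, atom_weights(heavy, weight))
    degree = [atom.GetDegree() for atom in heavy.GetAtoms()]
    for bond in heavy.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        val = 0.1 * bond.GetBondTypeAsDouble()
        if degree[i] == 1 or degree[j] == 1:
            val += 0.01
        b[i, j] = b[j, i] = val
    return b


def burden_eigenvalue(molecule: Molecule, rank: int, weight: str) -> DescriptorValue:
    """BEH: the ``rank``-th largest eigenvalue of the Burden matrix."""
    if molecule.num_heavy_atoms < rank:
        return DescriptorValue.missing("too-few-atoms")
    eigvals = np.linalg.eigvalsh(burden_matrix(molecule, weight))
    return DescriptorValue.of(np.sort(eigvals)[::-1][rank - 1])


# ---------------------------------------------------------------------------
# information indices

def _entropy_bits(class_sizes: list[int]) -> float:
    n = sum(class_sizes)
    return -sum((c / n) * math.log2(c / n) for c in class_sizes)


def atom_equivalence_classes(molecule: Molecule, order: int) -> list[int]:
    """Neighborhood-symmetry atom classes at the given refinement order.

    Atoms (hydrogens explicit) start in classes keyed by (element, degree,
    attached-H count) and are refined ``order`` times by the multiset of
    (neighbor class, bond order) pairs.
    """
    mol = molecule.with_hs
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    keys = [
        (a.GetSymbol(), a.GetDegree(), a.GetTotalNumHs(includeNeighbors=True))
        for a in mol.GetAtoms()
    ]
    classes = _canonicalize(keys)
    for _ in range(order):
        new_keys = []
        for a in mol.GetAtoms():
            nb = sorted(
                (classes[n.GetIdx()], mol.GetBondBetweenAtoms(a.GetIdx(), n.GetIdx()).GetBondTypeAsDouble())
                for n in a.GetNeighbors()
            )
            new_keys.append((classes[a.GetIdx()], tuple(nb)))
        classes = _canonicalize(new_keys)
    return classes


def _canonicalize(keys: list) -> list[int]:
    mapping: dict = {}
    out = []
    for k in keys:
        if k not in mapping:
            mapping[k] = len(mapping)
        out.append(mapping[k])
    return out


def information_content(molecule: Molecule, order: int) -> DescriptorValue:
    """IC_k: Shannon entropy (bits) of neighborhood-symmetry atom classes."""
    classes = atom_equivalence_classes(molecule, order)
    return DescriptorValue.of(_entropy_bits(list(Counter(classes).values())))


def vertex_degree_information(molecule: Molecule) -> DescriptorValue:
    """IVDE: entropy (bits) of vertex-degree classes on the H-depleted graph."""
    heavy = molecule.heavy
    if heavy.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    degs = Counter(a.GetDegree() for a in heavy.GetAtoms())
    return DescriptorValue.of(_entropy_bits(list(degs.values())))


# ---------------------------------------------------------------------------
# fragment counts

# C-009 "CHRX2": sp3 carbon bearing one H, one carbon substituent and two
# electronegative (X) substituents.
_C009_SMARTS = Chem.MolFromSmarts(
    "[CX4;H1]([#6])([N,O,S,P,F,Cl,Br,I])[N,O,S,P,F,Cl,Br,I]"
)


def atom_centered_fragment_C009(molecule: Molecule) -> DescriptorValue:
    """Count of carbons matching the CHRX2 atom-centered fragment."""
    matches = molecule.heavy.GetSubstructMatches(_C009_SMARTS)
    return DescriptorValue.of(len({m[0] for m in matches}))


def pair_frequency(molecule: Molecule, elem_a: str, elem_b: str, distance: int) -> DescriptorValue:
    """Count of unordered (elem_a, elem_b) pairs at a topological distance."""
    heavy = molecule.heavy
    symbols = [a.GetSymbol() for a in heavy.GetAtoms()]
    if elem_a not in symbols or elem_b not in symbols:
        return DescriptorValue.of(0)
    d = topological_distance_matrix(heavy)
    n = 0
    for i in range(len(symbols)):
        for j in range(i + 1, len(symbols)):
            if d[i, j] == distance and {symbols[i], symbols[j]} == {elem_a, elem_b}:
                n += 1
    return DescriptorValue.of(n)


# ---------------------------------------------------------------------------
# Moriguchi logP and derived values

_SMARTS = {
    "nitro": Chem.MolFromSmarts("[NX3](=O)=O"),
    "nitro_charged": Chem.MolFromSmarts("[N+](=O)[O-]"),
    "carboxamide": Chem.MolFromSmarts("[NX3][CX3]=[OX1]"),
    "sulfonamide": Chem.MolFromSmarts("[NX3][SX4](=[OX1])=[OX1]"),
    "quaternary_n": Chem.MolFromSmarts("[NX4+]"),
    "n_oxide": Chem.MolFromSmarts("[NX3+][OX1-]"),
    "isothiocyanate": Chem.MolFromSmarts("N=C=S"),
    "thiocyanate": Chem.MolFromSmarts("SC#N"),
    "beta_lactam": Chem.MolFromSmarts("O=C1CCN1"),
    "carboxyl": Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),
    "amine": Chem.MolFromSmarts("[NX3;H2,H1;!$(NC=O);!$(N=*);!$(Na)]"),
    # ortho donor/acceptor pair on an aromatic ring: internal H-bond dummy
    "intra_hb": Chem.MolFromSmarts("[OX2H1,NX3H1,NX3H2]-c1ccccc1-[C,N,O;$([CX3]=O),$([NX3]),$([OX2])]"),
}

# Moriguchi 13-term regression coefficients (term definitions in methods note)
MLOGP_COEFFS = {
    "CX": 1.244, "NO": -1.017, "PRX": 0.406, "UB": -0.145, "HB": 0.511,
    "POL": 0.268, "AMP": -2.215, "ALK": 0.912, "RNG": -0.392, "QN": -3.684,
    "NO2": 0.474, "NCS": 1.582, "BLM": 0.773,
}
MLOGP_INTERCEPT = -1.041
MLOGP_EXPONENTS = {"CX": 0.6, "NO": 0.9, "UB": 0.8}

# Verhaar fish 96-h baseline toxicity, log LC50 expressed in mmol/l
BLTF96_SLOPE = -0.85
BLTF96_INTERCEPT = 1.61

_HALOGEN_CX = {"F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}


def _n_matches(mol, key) -> int:
    return len(mol.GetSubstructMatches(_SMARTS[key]))


def mlogp_terms(molecule: Molecule) -> dict[str, float]:
    """Structural term counts of the Moriguchi logP regression."""
    mol = molecule.heavy
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]

    cx = sum(1.0 for s in symbols if s == "C") + sum(_HALOGEN_CX.get(s, 0.0) for s in symbols)
    no = sum(1 for s in symbols if s in ("N", "O"))

    # proximity of N/O heteroatoms: +2 per bonded pair, +1 per pair separated
    # by one atom; -1 per carboxamide/sulfonamide group
    hetero = [i for i, s in enumerate(symbols) if s in ("N", "O")]
    prx = 0.0
    if len(hetero) >= 2:
        d = topological_distance_matrix(mol)
        for ii, i in enumerate(hetero):
            for j in hetero[ii + 1:]:
                if d[i, j] == 1:
                    prx += 2
                elif d[i, j] == 2:
                    prx += 1
    prx -= _n_matches(mol, "carboxamide") + _n_matches(mol, "sulfonamide")

    # unsaturation: double/triple bonds on the Kekule structure, nitro excluded
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    nitro_bonds = set()
    for pat in ("nitro", "nitro_charged"):
        for match in kek.GetSubstructMatches(_SMARTS[pat]):
            n_idx = match[0]
            for o_idx in match[1:]:
                nitro_bonds.add(frozenset((n_idx, o_idx)))
    ub = sum(
        1
        for b in kek.GetBonds()
        if b.GetBondTypeAsDouble() >= 2.0
        and frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) not in nitro_bonds
    )

    hb = 1.0 if mol.HasSubstructMatch(_SMARTS["intra_hb"]) else 0.0

    # polar substituents attached to aromatic atoms
    pol = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O", "F", "Cl", "Br", "I", "S") and not atom.GetIsAromatic():
            if any(nb.GetIsAromatic() for nb in atom.GetNeighbors()):
                pol += 1

    has_cooh = _n_matches(mol, "carboxyl") > 0
    has_amine = _n_matches(mol, "amine") > 0
    amp = 1.0 if (has_cooh and has_amine) else 0.0

    is_hydrocarbon = all(s == "C" for s in symbols)
    aromatic = any(a.GetIsAromatic() for a in mol.GetAtoms())
    alk = 1.0 if (is_hydrocarbon and not aromatic and ub <= 1) else 0.0

    ring_info = mol.GetRingInfo()
    has_nonbenzene_ring = any(
        not all(mol.GetAtomWithIdx(i).GetIsAromatic() and symbols[i] == "C" for i in ring)
        for ring in ring_info.AtomRings()
    )
    rng = 1.0 if (has_nonbenzene_ring and not is_hydrocarbon) else 0.0

    qn = 1.0 * _n_matches(mol, "quaternary_n") + 0.5 * _n_matches(mol, "n_oxide")
    no2 = float(max(_n_matches(mol, "nitro"), _n_matches(mol, "nitro_charged")))
    ncs = 1.0 * _n_matches(mol, "isothiocyanate") + 0.5 * _n_matches(mol, "thiocyanate")
    blm = 1.0 if _n_matches(mol, "beta_lactam") else 0.0

    return {
        "CX": cx, "NO": float(no), "PRX": prx, "UB": float(ub), "HB": hb,
        "POL": float(pol), "AMP": amp, "ALK": alk, "RNG": rng, "QN": qn,
        "NO2": no2, "NCS": ncs, "BLM": blm,
    }


def mlogp(molecule: Molecule) -> DescriptorValue:
    """Moriguchi octanol-water logP from the 13-term structural regression."""
    terms = mlogp_terms(molecule)
    total = MLOGP_INTERCEPT
    for name, count in terms.items():
        x = max(count, 0.0) ** MLOGP_EXPONENTS[name] if name in MLOGP_EXPONENTS and count > 0 else count
        total += MLOGP_COEFFS[name] * x
    return DescriptorValue.of(total)


def bltf96(molecule: Molecule, slope: float = BLTF96_SLOPE, intercept: float = BLTF96_INTERCEPT) -> DescriptorValue:
    """Verhaar fish 96-h baseline toxicity, linear in Moriguchi logP."""
    m = mlogp(molecule)
    return DescriptorValue.of(slope * m.value + intercept)


# ---------------------------------------------------------------------------
# drug-likeness

# Ghose-Viswanadhan-Wendoloski qualifying ranges (80% coverage) for the
# antidepressant class: (low, high) on AlogP, molar refractivity, molecular
# weight and total atom count.  Adopted constants; see methods note.
GVW_RANGES = {
    "depressant": {
        80: {"alogp": (1.36, 4.54), "mr": (63.0, 110.7), "mw": (219.0, 378.5), "natoms": (28, 52)},
    }
}


def gvw_druglike_index(molecule: Molecule, klass: str = "depressant", coverage: int = 80) -> DescriptorValue:
    """0/1 indicator: all four bulk properties inside the class ranges."""
    ranges = GVW_RANGES[klass][coverage]
    mol = molecule.with_hs
    props = {
        "alogp": Crippen.MolLogP(mol),
        "mr": Crippen.MolMR(mol),
        "mw": Descriptors.MolWt(mol),
        "natoms": mol.GetNumAtoms(),
    }
    ok = all(lo <= props[k] <= hi for k, (lo, hi) in ranges.items())
    return DescriptorValue.of(1.0 if ok else 0.0)


@dataclass(frozen=True)
class LipinskiProperties:
    mw: float
    alogp: float
    hbd: int
    hba: int


def lipinski_properties(molecule: Molecule) -> LipinskiProperties:
    """Rule-of-five inputs: MW (Da, incl. H), Ghose-Crippen AlogP, donor and
    acceptor counts.

    Donors: N/O heteroatoms bearing at least one hydrogen, counted once per
    heteroatom.  Acceptors: every N and O atom.
    """
    mol = molecule.heavy
    hbd = sum(
        1 for a in mol.GetAtoms()
        if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs(includeNeighbors=True) >= 1
    )
    hba = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
    return LipinskiProperties(
        mw=Descriptors.MolWt(mol),
        alogp=Crippen.MolLogP(mol),
        hbd=hbd,
        hba=hba,
    )
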
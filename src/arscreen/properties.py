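"""Per-element atomic property scales used as descriptor weights.

Four weighting schemes appear in the autocorrelation / Burden-eigenvalue
descriptors: atomic mass (``m``), van der Waals volume (``v``), Sanderson
electronegativity (``e``) and atomic polarizability (``p``); ``u`` means
unweighted (every atom weighs 1).  Values follow the tabulations used by
classical 2D/3D descriptor software (Todeschini & Consonni, *Handbook of
Molecular Descriptors*); vdW volumes in A^3, polarizabilities in A^3,
masses in Da, Sanderson electronegativities dimensionless.

Weights enter descriptor formulas scaled relative to carbon, so the carbon
row is exactly 1.0 under every scheme.
"""

from __future__ import annotations

import numpy as np

# symbol -> (mass, vdw volume, Sanderson electronegativity, polarizability)
ATOMIC_PROPERTIES: dict[str, tuple[float, float, float, float]] = {
    "H":  (1.008,   6.709,  2.592, 0.667),
    "B":  (10.811, 17.875,  2.275, 3.030),
    "C":  (12.011, 22.449,  2.746, 1.760),
    "N":  (14.007, 15.599,  3.194, 1.100),
    "O":  (15.999, 11.494,  3.654, 0.802),
    "F":  (18.998,  9.203,  4.000, 0.557),
    "Al": (26.982, 36.511,  1.714, 6.800),
    "Si": (28.086, 31.976,  2.138, 5.380),
    "P":  (30.974, 26.522,  2.515, 3.630),
    "S":  (32.066, 24.429,  2.957, 2.900),
    "Cl": (35.453, 23.228,  3.475, 2.180),
    "Fe": (55.845, 41.052,  2.000, 8.400),
    "Co": (58.933, 35.041,  2.000, 7.500),
    "Ni": (58.693, 17.157,  2.000, 6.800),
    "Cu": (63.546, 11.494,  2.033, 6.100),
    "Zn": (65.390, 38.351,  2.223, 7.100),
    "Br": (79.904, 31.059,  3.219, 3.050),
    "Sn": (118.710, 45.830, 2.298, 7.700),
    "I":  (126.904, 38.735, 2.778, 5.350),
}

_SCHEME_INDEX = {"m": 0, "v": 1, "e": 2, "p": 3}

#: descriptor-weighting scheme codes, ``u`` = unit weights
WEIGHT_SCHEMES = ("u", "m", "v", "e", "p")


class UnknownElementError(KeyError):
    """Raised when a molecule contains an element outside the property table."""


def raw_property(symbol: str, scheme: str) -> float:
    """Raw (unscaled) atomic property for one element under one scheme."""
    if scheme == "u":
        return 1.0
    try:
        return ATOMIC_PROPERTIES[symbol][_SCHEME_INDEX[scheme]]
    except KeyError as exc:
        if symbol not in ATOMIC_PROPERTIES:
            raise UnknownElementError(
                f"no atomic properties tabulated for element {symbol!r}"
            ) from exc
        raise


def carbon_scaled(symbol: str, scheme: str) -> float:
    """Atomic property divided by the carbon value (carbon -> 1.0 exactly)."""
    if scheme == "u":
        return 1.0
    return raw_property(symbol, scheme) / raw_property("C", scheme)


def atom_weights(rdmol, scheme: str, scaled: bool = True) -> np.ndarray:
    """Vector of per-atom weights for an RDKit molecule.

    Order follows the molecule's atom indices; ``scheme`` is one of
    :data:`WEIGHT_SCHEMES`.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    fn = carbon_scaled if scaled else raw_property
    return np.array([fn(a.GetSymbol(), scheme) for a in rdmol.GetAtoms()], dtype=float)
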
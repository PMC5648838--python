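"""Element lookup tables: covalent and van der Waals radii (Å).

Covalent radii follow Cordero et al. (single-bond values); van der Waals
radii follow Bondi with Rowland/Taylor amendments. Only elements that occur
in typical protein-ligand systems are tabulated; anything else falls back to
a generic carbon-like radius.
"""

from __future__ import annotations

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "NA": 1.66,
    "MG": 1.41,
    "P": 1.07,
    "S": 1.05,
    "CL": 1.02,
    "K": 2.03,
    "CA": 1.76,
    "MN": 1.39,
    "FE": 1.32,
    "ZN": 1.22,
    "SE": 1.20,
    "BR": 1.20,
    "I": 1.39,
}

VDW_RADIUS: dict[str, float] = {
    "H": 1.10,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NA": 2.27,
    "MG": 1.73,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.04,
    "ZN": 2.10,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}

#: Metal elements treated as positively charged coordination partners.
METALS = frozenset({"MN", "ZN", "MG", "CA", "FE", "NA", "K"})

DEFAULT_COVALENT = 0.77
DEFAULT_VDW = 1.70


def covalent_radius(element: str) -> float:
    return COVALENT_RADIUS.get(element.upper(), DEFAULT_COVALENT)


def vdw_radius(element: str) -> float:
    return VDW_RADIUS.get(element.upper(), DEFAULT_VDW)


def element_from_atom_name(name: str) -> str:
    """Derive an element symbol from a PDB atom name.

    Two-letter element symbols are only assumed when the stripped name
    matches a known two-letter element (MN, FE, ...); otherwise the first
    alphabetic character wins, per PDB v3 naming practice.
    """
    stripped = name.strip()
    upper = stripped.upper()
    if upper in COVALENT_RADIUS and len(upper) == 2:
        return upper.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"
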
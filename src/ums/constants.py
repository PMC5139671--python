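"""Shared amino-acid tables: letter codes, van der Waals radii, hydropathy."""

from __future__ import annotations

#: The 20 standard amino acids, one-letter codes, alphabetical.
AA_ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Non-standard residue names mapped onto a standard parent (selenomethionine).
NONSTANDARD_PARENT: dict[str, str] = {"MSE": "MET"}

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

#: Heavy-atom van der Waals radii (Angstrom), by element.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def hydropathy_unit(aa: str) -> float:
    """Kyte-Doolittle hydropathy rescaled to [0, 1] (1 = most hydrophobic)."""
    return (KYTE_DOOLITTLE[aa] + 4.5) / 9.0
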
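"""Rotamer library and ideal-geometry side-chain construction.

A rotamer is a discrete side-chain conformation (chi angles) with a prior
probability. The packaged library is coarse and backbone-independent (<= 5
rotamers per amino acid, rounded field-typical chi values and frequencies);
any tab-delimited file with the same columns can be substituted.

Side chains are built atom by atom from ideal bond lengths/angles via NeRF
placement; ring closure for Pro/His/Phe/Tyr/Trp is approximate (each ring
atom is placed from ideal internal coordinates, the closing bond is not
refined) — adequate for a steric/contact scorer, documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import AA_ALPHABET
from .geometry import dihedral, place_atom
from .structure import Atom, ResidueSite

__all__ = [
    "Rotamer",
    "RotamerLibrary",
    "load_rotamer_library",
    "build_side_chain",
    "measure_chis",
    "n_chi",
    "CHI_ATOMS",
]


@dataclass(frozen=True)
class Rotamer:
    chis: tuple[float, ...]
    probability: float


#: Atom 4-tuples defining chi_1..chi_4 for each amino acid.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "A": [],
    "G": [],
    "C": [("N", "CA", "CB", "SG")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "V": [("N", "CA", "CB", "CG1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "K": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "R": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
}


def n_chi(aa: str) -> int:
    return len(CHI_ATOMS[aa])


# Internal-coordinate templates: (name, element, (A, B, P), bond, angle, torsion)
# where the new atom X is bonded to P, angle is B-P-X, torsion is A-B-P-X,
# and torsion is either ("chi", k, offset) -> chi_k + offset, or ("fixed", v).
_CB = ("CB", "C", ("N", "C", "CA"), 1.530, 110.5, ("fixed", -122.6))

SIDECHAIN_TEMPLATES: dict[str, list] = {
    "G": [],
    "A": [_CB],
    "C": [_CB, ("SG", "S", ("N", "CA", "CB"), 1.808, 114.0, ("chi", 1, 0.0))],
    "S": [_CB, ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "T": [
        _CB,
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
    ],
    "V": [
        _CB,
        ("CG1", "C", ("N", "CA", "CB"), 1.527, 110.8, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.8, ("chi", 1, 122.0)),
    ],
    "I": [
        _CB,
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "L": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.0)),
    ],
    "P": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, ("chi", 2, 0.0)),
    ],
    "M": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.8, ("chi", 3, 0.0)),
    ],
    "F": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, ("fixed", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, ("fixed", 180.0)),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, ("fixed", 0.0)),
    ],
    "Y": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, ("fixed", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, ("fixed", 180.0)),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, ("fixed", 0.0)),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fixed", 180.0)),
    ],
    "W": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 2, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, ("fixed", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, ("fixed", 180.0)),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, ("fixed", 0.0)),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, ("fixed", 180.0)),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, ("fixed", 180.0)),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, ("fixed", 0.0)),
    ],
    "H": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.0, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.3, ("fixed", 180.0)),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, ("fixed", 180.0)),
    ],
    "D": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.5, ("chi", 2, 0.0)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.5, ("chi", 2, 180.0)),
    ],
    "N": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "E": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.5, ("chi", 3, 0.0)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.5, ("chi", 3, 180.0)),
    ],
    "Q": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "K": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "CD"), 1.508, 111.3, ("chi", 3, 0.0)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4, 0.0)),
    ],
    "R": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", "N", ("CB", "CG", "CD"), 1.460, 111.5, ("chi", 3, 0.0)),
        ("CZ", "C", ("CG", "CD", "NE"), 1.330, 124.2, ("chi", 4, 0.0)),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.330, 120.0, ("fixed", 0.0)),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.330, 120.0, ("fixed", 180.0)),
    ],
}


@dataclass
class RotamerLibrary:
    """Per-amino-acid side-chain conformations with prior probabilities."""

    rotamers: dict[str, list[Rotamer]]

    def __post_init__(self) -> None:
        self.validate()

    def get(self, aa: str) -> list[Rotamer]:
        return self.rotamers[aa]

    def validate(self) -> None:
        for aa in AA_ALPHABET:
            if aa not in self.rotamers or not self.rotamers[aa]:
                raise ValueError(f"rotamer library missing amino acid {aa}")
            total = sum(r.probability for r in self.rotamers[aa])
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"rotamer probabilities for {aa} sum to {total}, not 1")
            for r in self.rotamers[aa]:
                if len(r.chis) != n_chi(aa):
                    raise ValueError(
                        f"{aa}: rotamer has {len(r.chis)} chi angles, expected {n_chi(aa)}"
                    )
        for aa in ("A", "G"):
            if len(self.rotamers[aa]) != 1 or self.rotamers[aa][0].chis != ():
                raise ValueError(f"{aa} must have exactly one empty-chi rotamer")

    def nearest_index(self, aa: str, chis: tuple[float, ...]) -> int:
        """Index of the library rotamer closest to observed chi angles
        (smallest maximum circular chi deviation)."""
        rots = self.rotamers[aa]
        if n_chi(aa) == 0 or not chis:
            return 0
        best, best_d = 0, float("inf")
        for i, r in enumerate(rots):
            d = max(_circ_diff(a, b) for a, b in zip(r.chis, chis))
            if d < best_d - 1e-12:
                best, best_d = i, d
        return best


def _circ_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def load_rotamer_library(path: str | Path | None = None) -> RotamerLibrary:
    """Load a rotamer library from a tab-delimited file (packaged default)."""
    if path is None:
        text = resources.files("ums").joinpath("data/rotamers.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, list[Rotamer]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"malformed rotamer line: {line!r}")
        aa = parts[0].strip()
        chis = tuple(float(p) for p in parts[1:5] if p.strip())
        prob = float(parts[5])
        table.setdefault(aa, []).append(Rotamer(chis=chis, probability=prob))
    return RotamerLibrary(table)


_DEFAULT_LIBRARY: RotamerLibrary | None = None


def default_library() -> RotamerLibrary:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = load_rotamer_library()
    return _DEFAULT_LIBRARY


def build_side_chain(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, aa: str, chis: tuple[float, ...]
) -> list[Atom]:
    """Construct side-chain heavy atoms for ``aa`` at the given chi angles,
    anchored on the backbone N/CA/C coordinates. Deterministic."""
    if len(chis) != n_chi(aa):
        raise ValueError(f"{aa} requires {n_chi(aa)} chi angles, got {len(chis)}")
    coords: dict[str, np.ndarray] = {
        "N": np.asarray(n, float),
        "CA": np.asarray(ca, float),
        "C": np.asarray(c, float),
    }
    atoms: list[Atom] = []
    for name, element, (ra, rb, rp), bond, angle, tors in SIDECHAIN_TEMPLATES[aa]:
        if tors[0] == "chi":
            torsion = chis[tors[1] - 1] + tors[2]
        else:
            torsion = tors[1]
        xyz = place_atom(coords[ra], coords[rb], coords[rp], bond, angle, torsion)
        coords[name] = xyz
        atoms.append(Atom(name=name, element=element, coord=xyz, is_sidechain=True))
    return atoms


def measure_chis(site: ResidueSite) -> tuple[float, ...]:
    """Chi angles (degrees) measured from a site's current coordinates.

    Returns as many angles as the residue's atoms allow; missing side-chain
    atoms truncate the tuple.
    """
    chis: list[float] = []
    for quad in CHI_ATOMS[site.aa]:
        try:
            pts = [site.atom(nm).coord for nm in quad]
        except KeyError:
            break
        chis.append(dihedral(*pts))
    return tuple(chis)
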
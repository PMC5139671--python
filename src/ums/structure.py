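"""Protein structure data model and PDB I/O.

The scan operates on a flat, immutable-ish view of a structure: an ordered
list of residue sites, each holding its heavy atoms with coordinates. Parsing
goes through Biopython's PDB parser (first MODEL only, highest-occupancy
altloc, waters/heteroatoms excluded); writing emits plain ATOM records at PDB
precision (3 decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .constants import (
    BACKBONE_ATOMS,
    NONSTANDARD_PARENT,
    ONE_TO_THREE,
    THREE_TO_ONE,
)

logger = logging.getLogger("ums")

__all__ = [
    "Atom",
    "ResidueSite",
    "StructureModel",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be turned into a usable structure."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    is_sidechain: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.name:
            raise ValueError("atom name must be nonempty")


@dataclass
class ResidueSite:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        """Author-style residue label, e.g. ``A23`` or ``A23B`` (icode)."""
        return f"{self.aa}{self.seq_number}{self.insertion_code}".strip()

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not found in residue {self.label}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_scannable(self) -> bool:
        """A site is scannable when all four backbone atoms are present."""
        return all(self.has_atom(n) for n in BACKBONE_ATOMS)

    def backbone_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_sidechain]

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_sidechain]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    id: str
    sites: list[ResidueSite]
    source: str = "memory"
    parse_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue identifiers in structure")

    @property
    def sequence(self) -> str:
        return "".join(s.aa for s in self.sites)

    def scannable_sites(self) -> list[ResidueSite]:
        return [s for s in self.sites if s.is_scannable]

    def all_atoms(self) -> list[tuple[int, Atom]]:
        """(site ordinal, atom) pairs over the whole structure."""
        return [(i, a) for i, s in enumerate(self.sites) for a in s.atoms]

    def copy(self) -> "StructureModel":
        sites = [
            ResidueSite(
                s.chain_id,
                s.seq_number,
                s.insertion_code,
                s.aa,
                [Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.is_sidechain) for a in s.atoms],
            )
            for s in self.sites
        ]
        return StructureModel(self.id, sites, source=self.source)


def _is_sidechain_name(name: str) -> bool:
    return name not in ("N", "CA", "C", "O", "OXT")


def parse_pdb(path: str | Path, chain_filter: set[str] | None = None) -> StructureModel:
    """Read MODEL 1 of a PDB file into a :class:`StructureModel`.

    Only standard amino-acid residues are kept (MSE is mapped to Met); the
    highest-occupancy altloc wins, ties broken by altloc label order
    (Biopython's disorder selection). Waters, other heteroatoms and
    non-standard residues are excluded but tallied in ``parse_report``.

    Parameters
    ----------
    path : file path to a PDB file containing at least one ATOM record.
    chain_filter : optional set of chain identifiers to retain.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise PDBParseError(f"{path}: no ATOM records found")
    model = models[0]

    available = [c.id for c in model]
    if chain_filter is not None:
        missing = set(chain_filter) - set(available)
        if missing:
            raise PDBParseError(
                f"{path}: chain(s) {sorted(missing)} not present; "
                f"available chains: {sorted(available)}"
            )

    report = {"waters": 0, "hetero_excluded": 0, "nonstandard_excluded": 0, "mse_mapped": 0}
    sites: list[ResidueSite] = []
    for chain in model:
        if chain_filter is not None and chain.id not in chain_filter:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            if resname == "HOH":
                report["waters"] += 1
                continue
            if resname in NONSTANDARD_PARENT:
                resname = NONSTANDARD_PARENT[resname]
                report["mse_mapped"] += 1
            elif hetflag.strip():
                report["hetero_excluded"] += 1
                continue
            if resname not in THREE_TO_ONE:
                report["nonstandard_excluded"] += 1
                logger.warning("excluding non-standard residue %s %s%s", resname, chain.id, resseq)
                continue
            atoms = []
            for atom in residue:  # disordered atoms yield the selected altloc
                if atom.element == "H" or atom.name.startswith("H"):
                    continue
                name = "SD" if atom.name == "SE" else atom.name  # MSE -> MET
                element = "S" if atom.element == "SE" else atom.element
                atoms.append(
                    Atom(
                        name=name,
                        element=element or name[0],
                        coord=np.array(atom.coord, dtype=float),
                        occupancy=float(atom.get_occupancy() or 1.0),
                        is_sidechain=_is_sidechain_name(name),
                    )
                )
            site = ResidueSite(chain.id, int(resseq), (icode or "").strip(), THREE_TO_ONE[resname], atoms)
            if not site.is_scannable:
                logger.warning("site %s/%s lacks full backbone; flagged unscannable", chain.id, resseq)
            sites.append(site)

    if not sites:
        raise PDBParseError(f"{path}: no standard amino-acid ATOM records found")
    m = StructureModel(path.stem, sites, source=str(path))
    m.parse_report = report
    return m


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as plain PDB ATOM records (one MODEL, TER per chain)."""
    if not model.sites:
        raise ValueError("cannot write an empty structure")
    path = Path(path)
    lines: list[str] = []
    serial = 1
    prev_chain: str | None = None
    for site in model.sites:
        if prev_chain is not None and site.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = site.chain_id
        resname = ONE_TO_THREE[site.aa]
        for atom in site.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {site.chain_id:1s}"
                f"{site.seq_number:4d}{site.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
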
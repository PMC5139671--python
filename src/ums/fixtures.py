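"""Synthetic structure fixtures: ideal helices, hairpins, compact balls.

These stand in for real PDB files so the whole pipeline runs offline. Side
chains are built by the package's own rotamer-placement machinery and then
relaxed by deterministic greedy descent to the per-site optimal library
rotamer, so an identity re-placement reproduces them bit-for-bit and the
native conformation is the scorer's optimum (identity ΔΔG = 0 exactly).
"""

from __future__ import annotations

import numpy as np

from .constants import AA_ALPHABET
from .geometry import place_atom
from .rotamers import build_side_chain, n_chi
from .scan import ScanConfig, score_site
from .structure import Atom, ResidueSite, StructureModel

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("helix", "hairpin", "compact_ball")

# ideal backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5


def _backbone_from_dihedrals(phi: np.ndarray, psi: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Chain of N/CA/C/O coordinates from per-residue phi/psi (omega = 180)."""
    n = len(phi)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(n):  # one extra virtual N to place the last O
        N.append(place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi[i]))
        if i == n - 1:
            break
        CA.append(place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(place_atom(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C, phi[i + 1]))
    out = []
    for i in range(n):
        O = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        out.append({"N": N[i], "CA": CA[i], "C": C[i], "O": O})
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _snake_lattice(n: int, spacing: float) -> np.ndarray:
    """Serpentine path through a near-cubic lattice (consecutive points are
    one spacing apart), producing a compact blob with interior points."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts = []
    for iz in range(side):
        ys = range(side) if iz % 2 == 0 else range(side - 1, -1, -1)
        for iy in ys:
            xs = range(side) if (iy + iz) % 2 == 0 else range(side - 1, -1, -1)
            for ix in xs:
                pts.append((ix, iy, iz))
                if len(pts) == n:
                    return spacing * np.array(pts, dtype=float)
    return spacing * np.array(pts[:n], dtype=float)


def _ball_backbone(n: int, spacing: float, rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    ca = _snake_lattice(n, spacing)
    ang = np.radians(_A_N_CA_C)
    u_n = np.array([1.0, 0.0, 0.0])
    u_c = np.array([np.cos(ang), np.sin(ang), 0.0])
    out = []
    for i in range(n):
        rot = _random_rotation(rng)
        N = ca[i] + _B_N_CA * (rot @ u_n)
        C = ca[i] + _B_CA_C * (rot @ u_c)
        O = place_atom(N, ca[i], C, _B_C_O, _A_CA_C_O, -45.0)
        out.append({"N": N, "CA": ca[i], "C": C, "O": O})
    return out


def _relax_rotamers(model: StructureModel, rotamer_idx: list[int], config: ScanConfig,
                    max_sweeps: int = 20) -> None:
    """Greedy coordinate descent: set every side chain to its best-scoring
    library rotamer given the others, sweeping until a fixed point.

    Each accepted move strictly lowers the total energy, so the descent
    terminates; at the fixed point the native conformation of every site is
    per-site optimal, which makes identity ΔΔG exactly zero.
    """
    library = config.get_library()
    for _ in range(max_sweeps):
        changed = False
        for i, site in enumerate(model.sites):
            if n_chi(site.aa) == 0:
                continue
            rots = library.get(site.aa)
            backbone = [a for a in site.atoms if not a.is_sidechain]
            nn, ca, cc = (site.atom(nm).coord for nm in ("N", "CA", "C"))
            best_i = rotamer_idx[i]
            best_score = score_site(model, site, config).total
            for k in range(len(rots)):
                if k == rotamer_idx[i]:
                    continue
                cand = ResidueSite(
                    site.chain_id, site.seq_number, site.insertion_code, site.aa,
                    backbone + build_side_chain(nn, ca, cc, site.aa, rots[k].chis),
                )
                model.sites[i] = cand
                s = score_site(model, cand, config).total
                model.sites[i] = site
                if s < best_score - 1e-12:
                    best_score, best_i = s, k
            if best_i != rotamer_idx[i]:
                rotamer_idx[i] = best_i
                model.sites[i] = ResidueSite(
                    site.chain_id, site.seq_number, site.insertion_code, site.aa,
                    backbone + build_side_chain(nn, ca, cc, site.aa, rots[best_i].chis),
                )
                changed = True
        if not changed:
            return


def make_fixture(
    kind: str,
    n_residues: int,
    sequence: str | None = None,
    seed: int = 0,
    config: ScanConfig | None = None,
) -> StructureModel:
    """Build a deterministic synthetic structure.

    Parameters
    ----------
    kind : ``helix`` (ideal alpha helix, phi/psi = -57/-47), ``hairpin``
        (two beta strands joined by a turn) or ``compact_ball`` (serpentine
        lattice packing with buried interior residues for n >= ~30).
    n_residues : chain length (>= 3).
    sequence : one-letter amino-acid string (default: seeded random draw).
    seed : drives the sequence draw, initial rotamer draws and (for
        compact_ball) the per-residue backbone orientations.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if n_residues < 3:
        raise ValueError("fixtures need at least 3 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AA_ALPHABET), size=n_residues))
    else:
        rng.choice(list(AA_ALPHABET), size=n_residues)  # keep stream position stable
    if len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"non-standard amino-acid letters in sequence: {sorted(bad)}")

    if kind == "helix":
        phi = np.full(n_residues, -57.0)
        psi = np.full(n_residues, -47.0)
        backbone = _backbone_from_dihedrals(phi, psi)
    elif kind == "hairpin":
        phi = np.full(n_residues, -120.0)
        psi = np.full(n_residues, 130.0)
        mid = n_residues // 2
        phi[mid - 1 : mid + 1] = (-60.0, -90.0)
        psi[mid - 1 : mid + 1] = (-30.0, 0.0)
        backbone = _backbone_from_dihedrals(phi, psi)
    else:
        backbone = _ball_backbone(n_residues, spacing=4.3, rng=rng)

    config = config or ScanConfig()
    library = config.get_library()
    sites: list[ResidueSite] = []
    rotamer_idx: list[int] = []
    for i, aa in enumerate(sequence):
        bb = backbone[i]
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", bb["O"]),
        ]
        rots = library.get(aa)
        probs = np.array([r.probability for r in rots])
        k = int(rng.choice(len(rots), p=probs / probs.sum()))
        atoms += build_side_chain(bb["N"], bb["CA"], bb["C"], aa, rots[k].chis)
        sites.append(ResidueSite("A", i + 1, "", aa, atoms))
        rotamer_idx.append(k)

    model = StructureModel(f"{kind}_{n_residues}_seed{seed}", sites, source="fixture")
    _relax_rotamers(model, rotamer_idx, config)
    return model
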
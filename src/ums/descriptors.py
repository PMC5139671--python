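"""Per-residue descriptors: average propensity, foldability, entropy, depth.

For each structure position the N×20 propensity row is summarized as

* **average propensity** — arithmetic mean over the 19 missense entries
  (the identity column is excluded: it describes no substitution);
* **foldability** — 1 − n_severe/19, where n_severe counts missense entries
  at or above a severity threshold (default 0.9). A count-based score: it
  tallies the severe mutations at a position without being influenced by the
  magnitude of the milder ones; low foldability flags residues critical for
  folding. (The count-based formula is this package's reconstruction of a
  qualitatively-described quantity.)
* **informational (Shannon) entropy** — H = Σ_x P(x)·log2(1/P(x)) over the
  row's propensities discretized into bins (default width 0.1, i.e. 11 bins
  by rounding; all 20 entries included by default). A position whose
  propensities are split between 0 and 1 is *more* entropic than one sitting
  uniformly at 0.5, although both average 0.5.
* **residue depth** — mean distance of the residue's heavy atoms from the
  solvent-accessible surface (Å), computed by probe-sphere surface sampling
  (no external MSMS binary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import AA_ALPHABET, vdw_radius
from .structure import StructureModel
from .thermo import MutationMatrix

__all__ = [
    "ResidueDescriptor",
    "average_propensity",
    "foldability",
    "informational_entropy",
    "residue_depth",
    "build_descriptors",
]


@dataclass(frozen=True)
class ResidueDescriptor:
    chain_id: str
    seq_number: int
    insertion_code: str
    wt_aa: str
    avg_propensity: float
    foldability: float
    entropy: float
    depth: float


def _missense(row: np.ndarray, wt_aa: str) -> np.ndarray:
    row = np.asarray(row, float)
    if row.shape != (20,):
        raise ValueError(f"expected a 20-entry propensity row, got shape {row.shape}")
    keep = np.ones(20, bool)
    keep[AA_ALPHABET.index(wt_aa)] = False
    return row[keep]


def average_propensity(row: np.ndarray, wt_aa: str) -> float:
    """Mean unfolding propensity over the 19 missense entries of a row."""
    return float(np.mean(_missense(row, wt_aa)))


def foldability(row: np.ndarray, wt_aa: str, severity_threshold: float = 0.9) -> float:
    """1 − (severe missense count)/19, severe meaning propensity >= threshold."""
    if not 0.5 < severity_threshold <= 1.0:
        raise ValueError("severity threshold must lie in (0.5, 1]")
    vals = _missense(row, wt_aa)
    n_severe = int(np.sum(vals >= severity_threshold))
    return 1.0 - n_severe / 19.0


def informational_entropy(row: np.ndarray, bin_width: float = 0.1) -> float:
    """Shannon entropy (bits) of the row's propensities after discretization
    to bins of ``bin_width`` (entries assigned by rounding to the nearest
    bin center; 0·log(1/0) taken as 0)."""
    row = np.asarray(row, float)
    nbins = 1.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin width must divide 1 evenly")
    bins = np.round(row / bin_width).astype(int)
    _, counts = np.unique(bins, return_counts=True)
    p = counts / row.size
    return float(np.sum(p * np.log2(1.0 / p)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pose-canonicalizing frame (centroid + sign-fixed principal axes) so
    the sampled surface — and hence depth — is invariant under rigid motion
    of the input structure."""
    center = coords.mean(axis=0)
    x = coords - center
    if len(x) < 2:
        return center, np.eye(3)
    cov = x.T @ x
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(3):
        proj = x @ vecs[:, k]
        s = np.sum(proj**3)
        if abs(s) < 1e-9:
            s = proj[np.argmax(np.abs(proj))]
        if s < 0:
            vecs[:, k] = -vecs[:, k]
    return center, vecs


def sample_sas_points(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Solvent-accessible-surface point cloud by probe-sphere sampling:
    points on each atom's expanded sphere (r_vdw + probe) that fall inside no
    other atom's expanded sphere. Directions are taken in the structure's
    canonical frame, making the cloud rigid-motion covariant."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    center, frame = _canonical_frame(coords)
    unit = _fibonacci_sphere(n_sphere_points) @ frame.T
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = float(expanded.max())
    kept: list[np.ndarray] = []
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbor_idx = tree.query_ball_point(coords[i], 2.0 * max_reach)
        neighbor_idx = [j for j in neighbor_idx if j != i]
        if neighbor_idx:
            nc = coords[neighbor_idx]
            nr = expanded[neighbor_idx]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            inside = (d2 < (nr**2)[None, :] - 1e-9).any(axis=1)
            pts = pts[~inside]
        if len(pts):
            kept.append(pts)
    if not kept:  # fully sealed (cannot happen for finite molecules)
        return np.empty((0, 3))
    return np.vstack(kept)


def residue_depth(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[tuple[str, int, str], float]:
    """Residue depth (Å) for every site: each atom's depth is its distance
    to the nearest sampled solvent-accessible-surface point, and the residue
    depth is the mean over the residue's heavy atoms. Deterministic for a
    fixed ``n_sphere_points``."""
    pairs = model.all_atoms()
    if not pairs:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coord for _, a in pairs])
    radii = np.array([vdw_radius(a.element) for _, a in pairs])
    surface = sample_sas_points(coords, radii, probe_radius, n_sphere_points)
    stree = cKDTree(surface)
    atom_depth, _ = stree.query(coords)
    depths: dict[tuple[str, int, str], float] = {}
    owners = np.array([i for i, _ in pairs])
    for i, site in enumerate(model.sites):
        depths[site.key] = float(np.mean(atom_depth[owners == i]))
    return depths


def build_descriptors(
    matrix: MutationMatrix,
    depths: dict[tuple[str, int, str], float],
    severity_threshold: float = 0.9,
    bin_width: float = 0.1,
    entropy_includes_identity: bool = True,
) -> list[ResidueDescriptor]:
    """Join the propensity matrix with the depth map into one descriptor per
    site (keyed join on (chain, number, icode); a mismatch is an error)."""
    missing = [k for k in matrix.row_keys if k not in depths]
    if missing:
        raise KeyError(f"depth map lacks matrix site(s): {missing[:5]}")
    out: list[ResidueDescriptor] = []
    for key, wt_aa, row in zip(matrix.row_keys, matrix.wt_aas, matrix.values):
        ent_row = row if entropy_includes_identity else _missense(row, wt_aa)
        out.append(
            ResidueDescriptor(
                chain_id=key[0],
                seq_number=key[1],
                insertion_code=key[2],
                wt_aa=wt_aa,
                avg_propensity=average_propensity(row, wt_aa),
                foldability=foldability(row, wt_aa, severity_threshold),
                entropy=informational_entropy(ent_row, bin_width),
                depth=depths[key],
            )
        )
    return out
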
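"""Two-state unfolding propensity transform and mutation-matrix assembly.

A mutant's folding free energy under the linear extrapolation model is

    ΔG_mut = ΔG_wt − m·[D] − ΔΔG

and its equilibrium unfolded population (the *unfolding propensity*) is the
two-state Boltzmann fraction

    P_u = 1 / (1 + exp(ΔG_mut / RT))

which anchors the universal 0–1 scale: 0 = fully stable, 0.5 = the
folding–unfolding equilibrium point (ΔG_mut = 0), 1 = completely unfolded.
Because the transform depends only on (ΔΔG, parameters), propensities from
different proteins are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AA_ALPHABET
from .scan import MutationRecord

__all__ = ["TransformParams", "MutationMatrix", "propensity", "build_matrix"]


@dataclass(frozen=True)
class TransformParams:
    """Knobs of the propensity transform.

    dg_wt : wild-type folding stability ΔG_wt in kcal/mol (default 5.0, a
        typical globular-protein stability — a calibration choice, which puts
        the wild type near fully folded and the 0.5 crossing at ΔΔG = 5.0).
    rt : R·T in kcal/mol (default 0.593, 298 K).
    m_value : linear-extrapolation slope m in kcal/mol/M (default 1.0).
    denaturant : evaluation denaturant concentration [D] in M (default 0).
    """

    dg_wt: float = 5.0
    rt: float = 0.593
    m_value: float = 1.0
    denaturant: float = 0.0

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if self.m_value < 0:
            raise ValueError("m_value must be non-negative")
        if not np.isfinite(self.dg_wt):
            raise ValueError("dg_wt must be finite")


def propensity(ddg, params: TransformParams | None = None):
    """Unfolding propensity of a mutant with the given ΔΔG (kcal/mol).

    Accepts scalars or arrays; overflow-guarded (extremes clamp smoothly to
    0 or 1, never NaN). Strictly increasing in ΔΔG.
    """
    params = params or TransformParams()
    dg_mut = params.dg_wt - params.m_value * params.denaturant - np.asarray(ddg, float)
    x = np.clip(dg_mut / params.rt, -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(x))
    return float(out) if np.isscalar(ddg) or np.asarray(ddg).ndim == 0 else out


@dataclass
class MutationMatrix:
    """N×20 unfolding-propensity matrix: rows = structure positions (with
    their wild-type residues), columns = target amino acids, alphabetical."""

    row_keys: list[tuple[str, int, str]]  # (chain, number, icode)
    wt_aas: list[str]
    values: np.ndarray  # shape (N, 20), entries in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.row_keys), len(AA_ALPHABET)):
            raise ValueError("matrix shape does not match row labels")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("propensities must lie in [0, 1]")

    @property
    def row_labels(self) -> list[str]:
        return [
            f"{aa}{num}{icode}".strip()
            for (chain, num, icode), aa in zip(self.row_keys, self.wt_aas)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=list(AA_ALPHABET))


def build_matrix(
    records: list[MutationRecord], params: TransformParams | None = None
) -> MutationMatrix:
    """Assemble the N×20 matrix from scan records (order-independent: rows
    follow the first appearance of each site, i.e. structure order for a
    scan's output; every site must carry all 20 targets)."""
    params = params or TransformParams()
    col_of = {aa: j for j, aa in enumerate(AA_ALPHABET)}
    row_keys: list[tuple[str, int, str]] = []
    wt_aas: dict[tuple[str, int, str], str] = {}
    cells: dict[tuple[str, int, str], dict[str, float]] = {}
    for r in sorted(records, key=lambda r: (r.chain_id, r.seq_number, r.insertion_code)):
        if r.site_key not in cells:
            row_keys.append(r.site_key)
            cells[r.site_key] = {}
            wt_aas[r.site_key] = r.wt_aa
        cells[r.site_key][r.mut_aa] = r.ddg
    values = np.empty((len(row_keys), len(AA_ALPHABET)))
    for i, key in enumerate(row_keys):
        row = cells[key]
        missing = set(AA_ALPHABET) - set(row)
        if missing:
            raise ValueError(
                f"site {key} is missing target(s) {sorted(missing)}; "
                "a complete scan provides 20 records per site"
            )
        for aa, ddg in row.items():
            values[i, col_of[aa]] = propensity(ddg, params)
    return MutationMatrix(row_keys=row_keys, wt_aas=[wt_aas[k] for k in row_keys], values=values)
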
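"""Quality control: rotamer-based internal control and validation scoring.

The internal control "mutates each residue to itself": for every site it
scores each *alternative* library rotamer of the native amino acid against
the native conformation. On a well-refined model these self-substitution
ΔΔG values center on 0; their mean, SD, one-sample t-test p-value and 95%
confidence interval summarize model quality. Only the interaction terms
(clash, contact, burial) enter these ΔΔG values — the rotamer prior is a
statistical preference, not a strain of the model, and including it would
bias every alternative of a well-placed side chain positive.

The validation harness converts experimental ΔΔG values (e.g. a
ProTherm-derived table) to propensities with the same transform and scores
agreement by percent matching (three-class: stabilized / neutral /
destabilized around 0.5) and a Fit-Score (1 − mean absolute propensity
error; a reconstruction — the original formula is not public).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .constants import AA_ALPHABET
from .rotamers import build_side_chain, n_chi
from .scan import ScanConfig, score_site
from .structure import ResidueSite, StructureModel

__all__ = [
    "InternalControlResult",
    "ExperimentalRecord",
    "self_rotamer_ddgs",
    "control_statistics",
    "percent_matching",
    "fit_score",
    "load_experimental_table",
]


@dataclass(frozen=True)
class InternalControlResult:
    structure_id: str
    n: int
    mean_ddg: float
    sd_ddg: float
    p_value: float
    ci95: tuple[float, float]
    accepted: bool


@dataclass(frozen=True)
class ExperimentalRecord:
    position: int
    wt_aa: str
    mut_aa: str
    ddg_exp: float

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_ALPHABET or self.mut_aa not in AA_ALPHABET:
            raise ValueError(f"non-standard amino acid in record {self}")
        if not np.isfinite(self.ddg_exp):
            raise ValueError("experimental ΔΔG must be finite")


def _interaction_total(model: StructureModel, site: ResidueSite, config: ScanConfig) -> float:
    e = score_site(model, site, config)
    return e.clash + e.contact + e.burial


def self_rotamer_ddgs(model: StructureModel, config: ScanConfig | None = None) -> list[float]:
    """Self-substitution ΔΔG values: for every site with side-chain degrees
    of freedom, the interaction-energy change of swapping the native side
    chain for each *other* library rotamer of the same amino acid (the
    native conformation is excluded — the statistic probes conformational
    spread). Deterministic."""
    config = config or ScanConfig()
    library = config.get_library()
    out: list[float] = []
    for i, site in enumerate(model.sites):
        if not site.is_scannable or n_chi(site.aa) == 0:
            continue
        rots = library.get(site.aa)
        if len(rots) < 2:
            continue
        from .rotamers import measure_chis

        native_idx = library.nearest_index(site.aa, measure_chis(site))
        wt = _interaction_total(model, site, config)
        backbone = [a for a in site.atoms if not a.is_sidechain]
        nn, ca, cc = (site.atom(nm).coord for nm in ("N", "CA", "C"))
        for k, rot in enumerate(rots):
            if k == native_idx:
                continue
            cand = ResidueSite(
                site.chain_id, site.seq_number, site.insertion_code, site.aa,
                backbone + build_side_chain(nn, ca, cc, site.aa, rot.chis),
            )
            model.sites[i] = cand
            try:
                out.append(_interaction_total(model, cand, config) - wt)
            finally:
                model.sites[i] = site
    return out


def control_statistics(
    ddgs: list[float],
    structure_id: str = "",
    alpha: float = 0.05,
    mean_tolerance: float = 0.5,
    width_tolerance: float = 1.0,
) -> InternalControlResult:
    """Mean, sample SD, two-sided one-sample t-test against 0 and the
    (1 − alpha) confidence interval of self-substitution ΔΔG values.

    The model is *accepted* when |mean| <= ``mean_tolerance`` (kcal/mol) and
    the CI half-width <= ``width_tolerance`` — i.e. the control is centered
    near the expected ΔΔG of 0 with a tight interval. The raw p-value is
    always reported so a literal "p < 0.05" screen can also be applied.
    Zero-variance convention: p = 1 when the mean is also 0, else p = 0.
    """
    x = np.asarray(ddgs, float)
    n = x.size
    if n < 2:
        return InternalControlResult(structure_id, n, float(x.mean()) if n else float("nan"),
                                     float("nan"), float("nan"), (float("nan"), float("nan")),
                                     accepted=False)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        ci = (mean, mean)
    else:
        t_stat = mean / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
        tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
        half = tcrit * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    half_width = (ci[1] - ci[0]) / 2.0
    accepted = abs(mean) <= mean_tolerance and half_width <= width_tolerance
    return InternalControlResult(structure_id, int(n), mean, sd, p, ci, accepted)


def percent_matching(pred, exp, neutral_band: float = 0.1) -> float:
    """Percentage of mutants whose predicted and experimental propensities
    fall in the same class: stabilized (< 0.5 − band), neutral, or
    destabilized (> 0.5 + band)."""
    pred = np.asarray(pred, float)
    exp = np.asarray(exp, float)
    if pred.shape != exp.shape or pred.size == 0:
        raise ValueError("propensity vectors must be nonempty and equal-length")

    def classify(v: np.ndarray) -> np.ndarray:
        return np.where(v < 0.5 - neutral_band, -1, np.where(v > 0.5 + neutral_band, 1, 0))

    return float(100.0 * np.mean(classify(pred) == classify(exp)))


def fit_score(pred, exp) -> float:
    """1 − mean |pred − exp| on the universal 0–1 propensity scale
    (1 = perfect agreement). A reconstruction of the original Fit-Score."""
    pred = np.asarray(pred, float)
    exp = np.asarray(exp, float)
    if pred.shape != exp.shape or pred.size == 0:
        raise ValueError("propensity vectors must be nonempty and equal-length")
    return float(1.0 - np.mean(np.abs(pred - exp)))


def load_experimental_table(path: str | Path) -> list[ExperimentalRecord]:
    """Read a tab-delimited experimental ΔΔG table: position, wild-type
    residue, mutant residue, ΔΔG (kcal/mol). Lines starting with ``#`` and
    a ``position``-labelled header row are skipped."""
    records: list[ExperimentalRecord] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("position"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"malformed experimental record: {line!r}")
        records.append(
            ExperimentalRecord(int(parts[0]), parts[1].strip(), parts[2].strip(), float(parts[3]))
        )
    return records
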
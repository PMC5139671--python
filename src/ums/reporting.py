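"""Output artifacts and pipeline orchestration.

Five artifacts per run, matching the screen's published data layout:

* ``<base>_matrix.txt``      — tab-delimited N×20 propensity matrix
* ``<base>_descriptor.txt``  — per-residue descriptor table (5 columns:
  sequence, average propensity, foldability, entropy, depth)
* ``<base>_standard.html``   — self-contained heat map (blue 0 → white 0.5 →
  red 1, hover tooltips)
* ``<base>_cluster.html``    — agglomeratively clustered heat map with
  embedded dendrograms
* ``<base>_coloring.py``     — UCSF-Chimera command script coloring residues
  by foldability, plus ``<base>_foldability.attr`` (generic attribute table)

plus ``<base>_control.txt`` with the internal-control statistics. All
writers are pure functions of their inputs; reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import dendrogram, leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .constants import AA_ALPHABET
from .descriptors import ResidueDescriptor, build_descriptors, residue_depth
from .qc import InternalControlResult, control_statistics, self_rotamer_ddgs
from .scan import ScanConfig, run_scan
from .structure import StructureModel, parse_pdb
from .thermo import MutationMatrix, TransformParams, build_matrix

logger = logging.getLogger("ums")

__all__ = [
    "RunConfig",
    "PipelineError",
    "write_matrix",
    "read_matrix",
    "write_descriptor_file",
    "read_descriptor_file",
    "render_standard_heatmap",
    "render_clustered_heatmap",
    "write_structure_coloring",
    "write_control_report",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------- text files

def _row_label(key: tuple[str, int, str], wt_aa: str, multi_chain: bool) -> str:
    chain, num, icode = key
    base = f"{wt_aa}{num}{icode}".strip()
    return f"{chain}:{base}" if multi_chain else base


def write_matrix(matrix: MutationMatrix, path: str | Path) -> None:
    """Tab-delimited matrix: header = the 20 amino-acid codes, first column
    the wild-type residue with author numbering (e.g. ``A23``), propensities
    printed with 3 decimals."""
    path = Path(path)
    chains = {k[0] for k in matrix.row_keys}
    multi = len(chains) > 1
    lines = ["res\t" + "\t".join(AA_ALPHABET)]
    for key, wt, row in zip(matrix.row_keys, matrix.wt_aas, matrix.values):
        lines.append(
            _row_label(key, wt, multi) + "\t" + "\t".join(f"{v:.3f}" for v in row)
        )
    path.write_text("\n".join(lines) + "\n")


def _parse_label(label: str) -> tuple[tuple[str, int, str], str]:
    chain = "A"
    if ":" in label:
        chain, label = label.split(":", 1)
    wt = label[0]
    rest = label[1:]
    digits = "".join(c for c in rest if c.isdigit())
    icode = rest[len(digits):]
    return (chain, int(digits), icode), wt


def read_matrix(path: str | Path) -> MutationMatrix:
    """Read back a matrix file written by :func:`write_matrix`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    if tuple(header) != AA_ALPHABET:
        raise ValueError(f"{path}: unexpected matrix header {header}")
    row_keys, wt_aas, values = [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        key, wt = _parse_label(parts[0])
        row_keys.append(key)
        wt_aas.append(wt)
        values.append([float(v) for v in parts[1:]])
    return MutationMatrix(row_keys=row_keys, wt_aas=wt_aas, values=np.array(values))


_DESCRIPTOR_HEADER = ("sequence", "avg_propensity", "foldability", "entropy", "depth")


def write_descriptor_file(descriptors: list[ResidueDescriptor], path: str | Path) -> None:
    """Tab-delimited descriptor table, exactly 5 data columns in order:
    sequence (wild-type residue + number), average propensity, foldability,
    informational entropy (bits), residue depth (Å)."""
    if not descriptors:
        raise ValueError("no descriptors to write")
    chains = {d.chain_id for d in descriptors}
    multi = len(chains) > 1
    lines = ["\t".join(_DESCRIPTOR_HEADER)]
    for d in descriptors:
        label = _row_label((d.chain_id, d.seq_number, d.insertion_code), d.wt_aa, multi)
        lines.append(
            f"{label}\t{d.avg_propensity:.3f}\t{d.foldability:.3f}\t{d.entropy:.3f}\t{d.depth:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_descriptor_file(path: str | Path) -> list[ResidueDescriptor]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if tuple(lines[0].split("\t")) != _DESCRIPTOR_HEADER:
        raise ValueError(f"{path}: unexpected descriptor header")
    out = []
    for ln in lines[1:]:
        label, avg, fold, ent, dep = ln.split("\t")
        key, wt = _parse_label(label)
        out.append(
            ResidueDescriptor(key[0], key[1], key[2], wt, float(avg), float(fold),
                              float(ent), float(dep))
        )
    return out


# ---------------------------------------------------------------- heat maps

def _color(v: float) -> str:
    """Blue (0) → white (0.5) → red (1) hex color."""
    v = min(1.0, max(0.0, v))
    if v <= 0.5:
        t = v / 0.5
        r = g = int(round(255 * t))
        b = 255
    else:
        t = (v - 0.5) / 0.5
        r = 255
        g = b = int(round(255 * (1.0 - t)))
    return f"#{r:02x}{g:02x}{b:02x}"


_CELL = 18  # px


def _heatmap_svg(
    values: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    row_dendro: dict | None = None,
    col_dendro: dict | None = None,
) -> str:
    n, m = values.shape
    left = 90 + (80 if row_dendro else 0)
    top = 60 + (80 if col_dendro else 0)
    width = left + m * _CELL + 20
    height = top + n * _CELL + 20
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="monospace" font-size="11">'
    ]
    for j, lab in enumerate(col_labels):
        x = left + j * _CELL + _CELL // 2
        parts.append(f'<text x="{x}" y="{top - 6}" text-anchor="middle">{lab}</text>')
    for i, lab in enumerate(row_labels):
        y = top + i * _CELL + _CELL // 2 + 4
        parts.append(f'<text x="{left - 6}" y="{y}" text-anchor="end">{lab}</text>')
    for i in range(n):
        for j in range(m):
            v = values[i, j]
            x, y = left + j * _CELL, top + i * _CELL
            parts.append(
                f'<rect x="{x}" y="{y}" width="{_CELL}" height="{_CELL}" '
                f'fill="{_color(v)}" stroke="#cccccc" stroke-width="0.5">'
                f"<title>{row_labels[i]}&#8594;{col_labels[j]}: {v:.3f}</title></rect>"
            )

    def _draw_dendro(dd: dict, horizontal: bool) -> None:
        # scipy dendrogram coords: leaves at 5, 15, 25... along the leaf axis
        dmax = max((max(d) for d in dd["dcoord"]), default=1.0) or 1.0
        for xs, ys in zip(dd["icoord"], dd["dcoord"]):
            pts = []
            for leaf_pos, dist in zip(xs, ys):
                along = (horizontal and left or top) + (leaf_pos / 10.0) * _CELL + _CELL * 0.0
                depth_px = 75.0 * (dist / dmax)
                if horizontal:  # column dendrogram above the map
                    pts.append((along, top - 80 + (75.0 - depth_px) + 1))
                else:  # row dendrogram left of the map
                    pts.append((left - 80 + (75.0 - depth_px) + 1, along))
            d = " ".join(f"{px:.1f},{py:.1f}" for px, py in pts)
            parts.append(f'<polyline points="{d}" fill="none" stroke="#444444"/>')

    if col_dendro:
        _draw_dendro(col_dendro, horizontal=True)
    if row_dendro:
        _draw_dendro(row_dendro, horizontal=False)
    parts.append("</svg>")
    return "".join(parts)


def _html_page(title: str, svg: str, note: str = "") -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{title}</title></head>\n<body>\n<h2>{title}</h2>\n"
        f"<p>Unfolding propensity: <b style=\"color:#0000ff\">0 stabilized</b> &#8212; "
        f"0.5 folding&#8211;unfolding equilibrium &#8212; "
        f"<b style=\"color:#ff0000\">1 unfolded</b>. Hover a cell for the value.{note}</p>\n"
        f"{svg}\n</body></html>\n"
    )


def render_standard_heatmap(matrix: MutationMatrix, path: str | Path) -> None:
    """Self-contained HTML heat map in structure order; hover shows
    (position, mutation, propensity)."""
    svg = _heatmap_svg(matrix.values, matrix.row_labels, list(AA_ALPHABET))
    Path(path).write_text(_html_page("Mutation matrix (standard)", svg))


def render_clustered_heatmap(
    matrix: MutationMatrix,
    path: str | Path,
    linkage: str = "average",
    metric: str = "euclidean",
) -> None:
    """Agglomerative hierarchical clustering of rows and columns (default
    Euclidean/average linkage) with embedded dendrograms; falls back to the
    standard map for a single-row matrix."""
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    vals = matrix.values
    if vals.shape[0] < 2:
        logger.warning("clustered heat map needs >= 2 rows; writing standard map")
        render_standard_heatmap(matrix, path)
        return
    zr = scipy_linkage(pdist(vals, metric=metric), method=linkage)
    zc = scipy_linkage(pdist(vals.T, metric=metric), method=linkage)
    row_order = list(leaves_list(zr))
    col_order = list(leaves_list(zc))
    dd_r = dendrogram(zr, no_plot=True)
    dd_c = dendrogram(zc, no_plot=True)
    reordered = vals[np.ix_(row_order, col_order)]
    row_labels = [matrix.row_labels[i] for i in row_order]
    col_labels = [AA_ALPHABET[j] for j in col_order]
    svg = _heatmap_svg(reordered, row_labels, col_labels, row_dendro=dd_r, col_dendro=dd_c)
    Path(path).write_text(
        _html_page(
            "Mutation matrix (clustered)",
            svg,
            note=f" Rows/columns ordered by {linkage}-linkage {metric} clustering.",
        )
    )


# ------------------------------------------------- structure coloring script

def write_structure_coloring(
    model: StructureModel,
    descriptors: list[ResidueDescriptor],
    path: str | Path,
    attr_path: str | Path | None = None,
    criticality_cutoff: float = 0.5,
) -> None:
    """Write a UCSF-Chimera command script coloring each residue by its
    foldability (red = critical, blue = robust) and a generic per-residue
    attribute file. Residues below ``criticality_cutoff`` are flagged."""
    path = Path(path)
    if attr_path is None:
        attr_path = path.with_name(path.name.replace("_coloring.py", "") + "_foldability.attr")
    keys = {s.key for s in model.sites}
    missing = [d for d in descriptors if (d.chain_id, d.seq_number, d.insertion_code) not in keys]
    if missing:
        raise KeyError(f"descriptors reference sites absent from the model: {missing[:3]}")
    critical = [d for d in descriptors if d.foldability < criticality_cutoff]
    for d in critical:
        logger.warning(
            "critical residue %s%d%s (foldability %.3f)",
            d.wt_aa, d.seq_number, d.insertion_code, d.foldability,
        )

    script = [
        "# Residue coloring by foldability for UCSF Chimera.",
        "# Open the structure first, then run this script (File > Open).",
        "# Foldability 1 = no severe mutations at the position (blue);",
        "# 0 = every missense mutation is severe (red, folding-critical).",
        "from chimera import runCommand",
    ]
    for d in descriptors:
        spec = f":{d.seq_number}{d.insertion_code}.{d.chain_id}"
        script.append(
            f'runCommand("setattr r foldability {d.foldability:.3f} {spec}")'
        )
        script.append(f'runCommand("color {_color(1.0 - d.foldability)} {spec}")')
    if critical:
        script.append("# critical residues (foldability < %.2f):" % criticality_cutoff)
        script.append(
            "# "
            + ", ".join(f"{d.wt_aa}{d.seq_number}{d.insertion_code}" for d in critical)
        )
    path.write_text("\n".join(script) + "\n")

    attr = [
        "# per-residue foldability written by ums",
        "attribute: foldability",
        "match mode: 1-to-1",
        "recipient: residues",
    ]
    for d in descriptors:
        attr.append(f"\t:{d.seq_number}{d.insertion_code}.{d.chain_id}\t{d.foldability:.3f}")
    Path(attr_path).write_text("\n".join(attr) + "\n")


def read_attribute_file(path: str | Path) -> dict[tuple[str, int, str], float]:
    """Parse a foldability attribute file back into {site key: value}."""
    out: dict[tuple[str, int, str], float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("\t"):
            continue
        spec, value = line.strip().split("\t")
        respart, chain = spec.lstrip(":").split(".")
        digits = "".join(c for c in respart if c.isdigit())
        icode = respart[len(digits):]
        out[(chain, int(digits), icode)] = float(value)
    return out


def write_control_report(result: InternalControlResult, path: str | Path) -> None:
    lines = [
        "# internal control: self-rotamer ΔΔG statistics (expected mean 0)",
        "structure\tn\tmean_ddg\tsd_ddg\tp_value\tci95_low\tci95_high\taccepted",
        f"{result.structure_id}\t{result.n}\t{result.mean_ddg:.4f}\t{result.sd_ddg:.4f}"
        f"\t{result.p_value:.4g}\t{result.ci95[0]:.4f}\t{result.ci95[1]:.4f}\t{result.accepted}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ pipeline

@dataclass
class RunConfig:
    """Everything one scan run needs (CLI flags and config files map here)."""

    input: str | Path | None = None
    model: StructureModel | None = None  # alternative to `input`
    chains: set[str] | None = None
    transform: TransformParams = field(default_factory=TransformParams)
    scan: ScanConfig = field(default_factory=ScanConfig)
    severity_threshold: float = 0.9
    bin_width: float = 0.1
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    linkage: str = "average"
    criticality_cutoff: float = 0.5
    out_dir: str | Path = "."
    basename: str | None = None
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Parse → scan → transform → descriptors → internal control → write all
    artifacts. Returns a manifest {filename: sha256}. Any stage failure
    raises :class:`PipelineError` naming the stage, and partial outputs are
    removed."""
    logging.getLogger("ums").setLevel(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    if config.model is not None:
        model = config.model
    else:
        model = stage("parse", parse_pdb, config.input, config.chains)
    base = config.basename or model.id
    records = stage("scan", run_scan, model, config.scan)
    matrix = stage("transform", build_matrix, records, config.transform)
    depths = stage(
        "descriptors", residue_depth, model, config.probe_radius, config.n_sphere_points
    )
    descriptors = stage(
        "descriptors", build_descriptors, matrix, depths,
        config.severity_threshold, config.bin_width,
    )
    ddgs = stage("control", self_rotamer_ddgs, model, config.scan)
    control = stage("control", control_statistics, ddgs, model.id)

    outputs = {
        "matrix": out_dir / f"{base}_matrix.txt",
        "descriptor": out_dir / f"{base}_descriptor.txt",
        "standard": out_dir / f"{base}_standard.html",
        "cluster": out_dir / f"{base}_cluster.html",
        "coloring": out_dir / f"{base}_coloring.py",
        "attr": out_dir / f"{base}_foldability.attr",
        "control": out_dir / f"{base}_control.txt",
    }

    def _write_all():
        write_matrix(matrix, outputs["matrix"])
        written.append(outputs["matrix"])
        write_descriptor_file(descriptors, outputs["descriptor"])
        written.append(outputs["descriptor"])
        render_standard_heatmap(matrix, outputs["standard"])
        written.append(outputs["standard"])
        render_clustered_heatmap(matrix, outputs["cluster"], linkage=config.linkage)
        written.append(outputs["cluster"])
        write_structure_coloring(
            model, descriptors, outputs["coloring"], outputs["attr"],
            config.criticality_cutoff,
        )
        written.append(outputs["coloring"])
        written.append(outputs["attr"])
        write_control_report(control, outputs["control"])
        written.append(outputs["control"])

    stage("report", _write_all)
    n_sites = len(model.scannable_sites())
    logger.info(
        "pipeline complete: %d sites scanned, %d mutations evaluated, "
        "control n=%d, accepted=%s",
        n_sites, len(records), control.n, control.accepted,
    )
    return {p.name: _sha256(p) for p in outputs.values()}
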
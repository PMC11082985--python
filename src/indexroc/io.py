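"""Cohort CSV I/O, run configuration, and the end-to-end pipeline.

The cohort interchange format is a strict two-column CSV
(``value_ug_per_L``, ``diseased``), UTF-8, comma-separated, header
required, "." decimal.  Parsing is deliberately unforgiving: non-numeric
or negative values and labels outside {0, 1} are rejected with their row
numbers, and a decimal-comma file (a real hazard for European laboratory
exports) produces a dedicated message rather than a cryptic parse error.

:func:`run_full_analysis` chains the whole pipeline — metric table, CDA
curves, SS/PV-ROC, both index-ROC curves, index cut-off diagram with
unified crossing, reciprocal diagram, AOX summaries, plots and a text
report — into one output directory.  Every artifact embeds the SHA-256
hash of the fully serialized configuration, so a bundle is reproducible
from the ``config.json`` it ships with.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import plotting
from .bridge import QualitativeResult, gain_analysis, implied_cutoff
from .curves import (
    AnnotatedCurve,
    DEFAULT_GRID_VALUES,
    ThresholdGrid,
    cda_curves,
    curves_to_dataframe,
    index_roc,
    pv_roc,
    ss_roc,
)
from .metrics import Cohort, Comparator, metric_table
from .simulate import CohortSpec, generate_cohort
from .unified import aox, index_cutoff_diagram, reciprocal_diagram, unified_cutoff

__all__ = [
    "RunConfig",
    "read_cohort_csv",
    "run_full_analysis",
    "write_cohort_csv",
]

logger = logging.getLogger(__name__)

VALUE_COL = "value_ug_per_L"
LABEL_COL = "diseased"


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a cohort from the strict two-column CSV format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except Exception as exc:  # malformed beyond recovery
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in (VALUE_COL, LABEL_COL) if c not in df.columns]
    if missing:
        if len(df.columns) == 1 and ";" in df.columns[0]:
            raise ValueError(
                f"{path}: semicolon-separated file detected; this reader "
                "requires comma-separated CSV with '.' decimals"
            )
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    values = np.empty(len(df))
    diseased = np.empty(len(df), dtype=bool)
    for i, (raw_v, raw_d) in enumerate(zip(df[VALUE_COL], df[LABEL_COL])):
        row = i + 2  # 1-based, after header
        sv = str(raw_v).strip()
        if "," in sv:
            raise ValueError(
                f"{path}, row {row}: decimal comma in {sv!r} — "
                "use '.' as the decimal separator"
            )
        try:
            v = float(sv)
        except ValueError:
            raise ValueError(f"{path}, row {row}: non-numeric value {sv!r}") from None
        if not np.isfinite(v):
            raise ValueError(f"{path}, row {row}: non-finite value {sv!r}")
        if v < 0:
            raise ValueError(f"{path}, row {row}: negative value {v}")
        sd = str(raw_d).strip()
        if sd not in {"0", "1"}:
            raise ValueError(
                f"{path}, row {row}: disease label must be 0 or 1, got {sd!r}"
            )
        values[i] = v
        diseased[i] = sd == "1"
    return Cohort(values=values, diseased=diseased, meta=f"read from {path.name}")


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort in the interchange format (round-trips exactly:
    values use repr-precision floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{VALUE_COL},{LABEL_COL}\n")
        for v, d in zip(cohort.values, cohort.diseased):
            fh.write(f"{float(v)!r},{int(d)}\n")
    return path


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one analysis run."""

    input_path: Optional[str] = None  # None → simulate with `seed`
    grid: tuple[float, ...] = DEFAULT_GRID_VALUES
    detection_floor: float = 0.5
    comparator: Comparator = "ge"
    prevalence_override: Optional[float] = None
    qualitative: Optional[dict] = None  # se/sp/ppv/npv/label of a visual test
    outdir: str = "indexroc_out"
    plot_formats: tuple[str, ...] = ("svg",)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        ThresholdGrid(values=self.grid, detection_floor=self.detection_floor)
        if self.prevalence_override is not None and not (
            0.0 < self.prevalence_override < 1.0
        ):
            raise ValueError("prevalence override must lie in (0, 1)")
        for fmt in self.plot_formats:
            if fmt not in {"svg", "png"}:
                raise ValueError(f"unsupported plot format {fmt!r}")

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "grid": list(self.grid),
            "detection_floor": self.detection_floor,
            "comparator": self.comparator,
            "prevalence_override": self.prevalence_override,
            "qualitative": self.qualitative,
            "outdir": self.outdir,
            "plot_formats": list(self.plot_formats),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv_with_hash(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def _json_dump(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n", encoding="utf-8")


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete evaluation pipeline and write the report bundle.

    Returns a manifest dict mapping artifact names to paths.  Deterministic
    given the configuration (including the seed, when simulating).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash

    if config.input_path is not None:
        cohort = read_cohort_csv(config.input_path)
    else:
        cohort = generate_cohort(CohortSpec(seed=config.seed))
    cohort.require_both_classes()

    grid = ThresholdGrid(values=config.grid, detection_floor=config.detection_floor)
    usable = [t for t in grid.values if cohort.values.min() <= t <= cohort.values.max()]
    if not usable:
        raise ValueError(
            "no grid threshold lies inside the data range "
            f"[{cohort.values.min():.3g}, {cohort.values.max():.3g}] µg/L; "
            f"unusable thresholds: {list(grid.values)}"
        )

    table = metric_table(cohort, grid.values, config.comparator)
    manifest: dict[str, str] = {}

    # --- per-cutoff metric table -----------------------------------------
    mdf = pd.DataFrame([m.to_dict() for m in table])
    _write_csv_with_hash(mdf, outdir / "metrics.csv", cfg_hash)
    manifest["metrics"] = str(outdir / "metrics.csv")

    # --- curves ----------------------------------------------------------
    stage = "curve construction"
    try:
        cda = cda_curves(cohort, grid, config.comparator, table=table)
        ss = ss_roc(cohort, grid, config.comparator, table=table)
        pv = pv_roc(cohort, grid, config.comparator, table=table)
        ssj = index_roc(cohort, grid, "SS", config.comparator, table=table)
        pvpsi = index_roc(cohort, grid, "PV", config.comparator, table=table)
    except ValueError as exc:
        raise ValueError(f"{stage}: {exc}") from exc
    all_curves: list[AnnotatedCurve] = [*cda, ss, pv, ssj, pvpsi]
    _write_csv_with_hash(curves_to_dataframe(all_curves), outdir / "curves.csv", cfg_hash)
    manifest["curves"] = str(outdir / "curves.csv")

    # --- unified analysis ------------------------------------------------
    stage = "unified analysis"
    try:
        diagram = index_cutoff_diagram(cohort, grid, config.comparator, table=table)
        unified = unified_cutoff(diagram)
        recip = reciprocal_diagram(diagram)
        aox_j = aox(diagram.j_curve, family="SS")
        aox_psi = aox(diagram.psi_curve, family="PV")
    except ValueError as exc:
        raise ValueError(f"{stage}: {exc}") from exc
    _json_dump(unified.to_dict(), outdir / "unified.json", cfg_hash)
    _json_dump(
        {"aox": [aox_j.to_dict(), aox_psi.to_dict()]}, outdir / "aox.json", cfg_hash
    )
    manifest["unified"] = str(outdir / "unified.json")
    manifest["aox"] = str(outdir / "aox.json")

    # --- optional qualitative bridge -------------------------------------
    bridge_result = None
    if config.qualitative:
        stage = "qualitative bridge"
        try:
            qual = QualitativeResult(**config.qualitative)
            matched = "SS" if qual.has_ss else "PV"
            bridge_result = implied_cutoff(cda, qual, matched_on=matched)
            ref = min(grid.values, key=lambda t: abs(t - bridge_result.implied_cutoff))
            reader_pt = next(m for m in table if m.threshold == ref)
            gains = gain_analysis(reader_pt, qual)
            bridge_result = replace(bridge_result, gains=gains, reference_cutoff=ref)
        except ValueError as exc:
            raise ValueError(f"{stage}: {exc}") from exc
        _json_dump(bridge_result.to_dict(), outdir / "bridge.json", cfg_hash)
        manifest["bridge"] = str(outdir / "bridge.json")

    # --- plots -----------------------------------------------------------
    stage = "plotting"
    plots = {
        "cda": lambda ax: plotting.plot_cda(cda, ax=ax),
        "ss_roc": lambda ax: plotting.plot_roc(ss, ax=ax),
        "pv_roc": lambda ax: plotting.plot_roc(pv, ax=ax),
        "index_roc": lambda ax: plotting.plot_index_roc(ssj, pvpsi, ax=ax),
        "index_cutoff": lambda ax: plotting.plot_index_cutoff(diagram, unified, ax=ax),
        "reciprocal": lambda ax: plotting.plot_reciprocal(recip, ax=ax),
    }
    for name, fn in plots.items():
        for fmt in config.plot_formats:
            p = outdir / f"{name}.{fmt}"
            plotting.render(fn, p, title_suffix=f"config {cfg_hash}")
            manifest[f"plot_{name}_{fmt}"] = str(p)

    # --- text report ------------------------------------------------------
    prev = (
        config.prevalence_override
        if config.prevalence_override is not None
        else cohort.prevalence.p
    )
    lines = [
        f"indexroc analysis report (config {cfg_hash})",
        "=" * 46,
        f"cohort: n={len(cohort)} ({cohort.n_diseased} diseased / "
        f"{cohort.n_nondiseased} non-diseased), prevalence {prev:.3f}",
        f"grid (µg/L): {', '.join(f'{v:g}' for v in grid.values)}",
        f"positivity: value {'>=' if config.comparator == 'ge' else '>'} threshold",
        "",
        f"SS-ROC AUC (grid trapezoid): {ss.auc():.3f}",
        f"max SS-J index: {max(p.y for p in ssj.points):.3f}",
        f"max PV-PSI index: {max(p.y for p in pvpsi.points):.3f}",
        f"unified cut-off: {unified.method}"
        + (
            f" at {unified.cutoff_star:.1f} µg/L, index {unified.index_star:.3f}"
            if unified.cutoff_star is not None
            else ""
        ),
        f"AOX (SS-J, clipped at 0): {aox_j.area:.1f} index·µg/L "
        f"(mean level {aox_j.normalized:.3f})",
        f"AOX (PV-PSI, clipped at 0): {aox_psi.area:.1f} index·µg/L "
        f"(mean level {aox_psi.normalized:.3f})",
    ]
    if bridge_result is not None:
        lines.append(
            f"qualitative bridge ({bridge_result.matched_on}): implied cut-off "
            f"{bridge_result.implied_cutoff:.2f} µg/L; gains (pp): "
            + ", ".join(f"{k}={v:+.1f}" for k, v in (bridge_result.gains or {}).items())
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    manifest["report"] = str(outdir / "report.txt")

    _json_dump({"config": config.to_dict()}, outdir / "config.json", cfg_hash)
    manifest["config"] = str(outdir / "config.json")
    return manifest
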
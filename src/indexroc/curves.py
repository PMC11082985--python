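"""Curve families over a threshold grid.

Four families are built from the same per-threshold metric table:

* CDA curves — sensitivity, specificity, PPV, NPV plotted directly against
  the cut-off concentration (cumulative distribution analysis);
* SS-ROC — sensitivity vs 1−specificity, each point annotated with its
  generating cut-off (the "ROC curve with integrated cut-off distribution");
* PV-ROC — PPV vs 1−NPV, the predictive-value analogue.  No AUC exists for
  this curve kind: its axes do not span [0, 1] and the curve may occupy an
  arbitrarily small x-interval at low prevalence, so requesting one raises;
* index-ROC — Youden's J vs 1−Sp (SS family) or PSI vs 1−NPV (PV family).

Every curve point retains the full :class:`~indexroc.metrics.MetricPoint`
that produced it, so nothing is lost in projection: any point maps back to
its threshold and confusion counts.  Points whose metric is undefined at a
threshold (0/0) are dropped from the curve, recorded in ``curve.dropped``
and logged — never interpolated through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import Cohort, Comparator, MetricPoint, metric_table

__all__ = [
    "AnnotatedCurve",
    "CurveKind",
    "CurvePoint",
    "ThresholdGrid",
    "DEFAULT_GRID_VALUES",
    "cda_curves",
    "curve_by_kind",
    "index_roc",
    "pv_roc",
    "ss_roc",
    "curves_to_dataframe",
]

logger = logging.getLogger(__name__)

#: Preset concentration grid (µg/L) of the bladder-cancer worked example.
DEFAULT_GRID_VALUES: tuple[float, ...] = (5.0, 7.5, 10.0, 30.0, 50.0, 90.0, 110.0, 250.0, 300.0)


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing cut-off concentrations (µg/L).

    Values below the reader's detection floor (default 0.5 µg/L — no
    concentration below the quantitative detection limit is observable) are
    clipped up to the floor; duplicates arising from clipping are merged.
    """

    values: tuple[float, ...]
    detection_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.detection_floor < 0 or not np.isfinite(self.detection_floor):
            raise ValueError("detection floor must be finite and non-negative")
        raw = np.asarray(self.values, dtype=float)
        if raw.size == 0:
            raise ValueError("threshold grid must not be empty")
        if not np.all(np.isfinite(raw)):
            raise ValueError("thresholds must be finite")
        if np.any(np.diff(raw) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        clipped = np.maximum(raw, self.detection_floor)
        clipped = np.unique(clipped)
        object.__setattr__(self, "values", tuple(float(v) for v in clipped))

    @classmethod
    def default(cls, detection_floor: float = 0.5) -> "ThresholdGrid":
        return cls(values=DEFAULT_GRID_VALUES, detection_floor=detection_floor)

    @classmethod
    def empirical(cls, cohort: Cohort, detection_floor: float = 0.5) -> "ThresholdGrid":
        """All distinct observed values as thresholds (oracle/testing mode)."""
        vals = np.unique(np.maximum(cohort.values, detection_floor))
        return cls(values=tuple(float(v) for v in vals), detection_floor=detection_floor)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


class CurveKind(str, Enum):
    CDA_SE = "CDA_SE"
    CDA_SP = "CDA_SP"
    CDA_PPV = "CDA_PPV"
    CDA_NPV = "CDA_NPV"
    SS_ROC = "SS_ROC"
    PV_ROC = "PV_ROC"
    SSJ_INDEX_ROC = "SSJ_INDEX_ROC"
    PVPSI_INDEX_ROC = "PVPSI_INDEX_ROC"
    INDEX_CUTOFF = "INDEX_CUTOFF"
    RECIP_INDEX_CUTOFF = "RECIP_INDEX_CUTOFF"


@dataclass(frozen=True)
class CurvePoint:
    """One plotted point and the metric bundle that generated it."""

    cutoff: float
    x: float
    y: float
    metric: Optional[MetricPoint] = None


@dataclass
class AnnotatedCurve:
    """Ordered (cutoff, x, y) triples of one curve kind.

    Points are ordered by cut-off and each carries its generating cut-off
    (and, when built from a cohort, the full metric bundle) — the curve is
    lossless with respect to the thresholds that produced it.
    """

    kind: CurveKind
    points: list[CurvePoint]
    axis_labels: tuple[str, str]
    dropped: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cutoffs = [p.cutoff for p in self.points]
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("curve points must be strictly ordered by cutoff")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def cutoffs(self) -> np.ndarray:
        return np.array([p.cutoff for p in self.points], dtype=float)

    @property
    def xs(self) -> np.ndarray:
        return np.array([p.x for p in self.points], dtype=float)

    @property
    def ys(self) -> np.ndarray:
        return np.array([p.y for p in self.points], dtype=float)

    @property
    def span(self) -> tuple[float, float]:
        if not self.points:
            raise ValueError("empty curve has no span")
        return self.points[0].cutoff, self.points[-1].cutoff

    def auc(self) -> float:
        """Trapezoidal area under an SS-ROC curve.

        Virtual anchor points (0,0) (threshold → ∞: nobody positive) and
        (1,1) (threshold at/below the floor: everybody positive) are
        appended so the area is well defined on a coarse grid.  Duplicate x
        values collapse to their maximal y (the upper staircase).  Any other
        curve kind refuses: PV-ROC and the index-ROC curves have no AUC —
        their axes do not range over [0, 1].
        """
        if self.kind is not CurveKind.SS_ROC:
            raise TypeError(f"AUC is not defined for curve kind {self.kind.value}")
        x = np.concatenate(([0.0, 1.0], self.xs))
        y = np.concatenate(([0.0, 1.0], self.ys))
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        ux = np.unique(x)
        uy = np.array([y[x == v].max() for v in ux])
        return float(np.trapezoid(uy, ux))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy representation: one row per point, full metric columns."""
        rows = []
        for p in self.points:
            row: dict = {
                "kind": self.kind.value,
                "cutoff_ug_per_L": p.cutoff,
                "x": p.x,
                "y": p.y,
            }
            if p.metric is not None:
                m = p.metric.to_dict()
                for col in ("se", "sp", "ppv", "npv", "j", "psi", "tp", "fp", "tn", "fn"):
                    row[col] = m[col]
            rows.append(row)
        return pd.DataFrame(rows)


def curves_to_dataframe(curves: Sequence[AnnotatedCurve]) -> pd.DataFrame:
    return pd.concat([c.to_dataframe() for c in curves], ignore_index=True)


def curve_by_kind(curves: Sequence[AnnotatedCurve], kind: CurveKind) -> AnnotatedCurve:
    for c in curves:
        if c.kind is kind:
            return c
    raise KeyError(f"no curve of kind {kind.value} in family")


def _project(
    table: Sequence[MetricPoint],
    kind: CurveKind,
    point_fn,
    needed: Sequence[str],
    axis_labels: tuple[str, str],
) -> AnnotatedCurve:
    """Project a metric table onto (x, y), dropping undefined points."""
    points: list[CurvePoint] = []
    dropped: list[tuple[float, str]] = []
    for m in table:
        missing = [name for name in needed if getattr(m, name) is None]
        if missing:
            reason = f"undefined {', '.join(missing)}"
            dropped.append((m.threshold, reason))
            logger.info(
                "%s: dropping cutoff %g µg/L (%s)", kind.value, m.threshold, reason
            )
            continue
        x, y = point_fn(m)
        points.append(CurvePoint(cutoff=m.threshold, x=x, y=y, metric=m))
    if not points:
        raise ValueError(
            f"curve {kind.value}: metric(s) {', '.join(needed)} undefined at every threshold"
        )
    return AnnotatedCurve(kind=kind, points=points, axis_labels=axis_labels, dropped=dropped)


_CDA_SPECS = {
    CurveKind.CDA_SE: ("se", "sensitivity"),
    CurveKind.CDA_SP: ("sp", "specificity"),
    CurveKind.CDA_PPV: ("ppv", "PPV"),
    CurveKind.CDA_NPV: ("npv", "NPV"),
}


def cda_curves(
    cohort: Cohort,
    grid: ThresholdGrid,
    comparator: Comparator = "ge",
    table: Optional[Sequence[MetricPoint]] = None,
) -> list[AnnotatedCurve]:
    """Cumulative distribution analysis: Se, Sp, PPV and NPV each plotted
    against the cut-off value.

    With the ≥-positivity convention the Se curve is non-increasing and the
    Sp curve non-decreasing in the cut-off; PPV and NPV run in the same
    opposite-direction pattern on typical unimodal marker mixtures.
    """
    if table is None:
        table = metric_table(cohort, grid.values, comparator)
    out = []
    for kind, (attr, label) in _CDA_SPECS.items():
        out.append(
            _project(
                table,
                kind,
                lambda m, a=attr: (m.threshold, getattr(m, a)),
                (attr,),
                ("cut-off (µg/L)", label),
            )
        )
    return out


def ss_roc(
    cohort: Cohort,
    grid: ThresholdGrid,
    comparator: Comparator = "ge",
    table: Optional[Sequence[MetricPoint]] = None,
) -> AnnotatedCurve:
    """SS-ROC: sensitivity vs 1−specificity, cut-off annotated per point.

    Cut-offs increase from the top-right corner of the plot toward the
    bottom-left (raising the threshold trades sensitivity for specificity).
    """
    if table is None:
        table = metric_table(cohort, grid.values, comparator)
    return _project(
        table,
        CurveKind.SS_ROC,
        lambda m: (1.0 - m.sp, m.se),
        ("se", "sp"),
        ("1 − specificity", "sensitivity"),
    )


def pv_roc(
    cohort: Cohort,
    grid: ThresholdGrid,
    comparator: Comparator = "ge",
    table: Optional[Sequence[MetricPoint]] = None,
) -> AnnotatedCurve:
    """PV-ROC: PPV vs 1−NPV.  Prevalence-dependent; at low prevalence the
    curve occupies a narrow x-interval near 0.  Cut-offs run opposite to
    the SS-ROC direction.  ``auc()`` on this curve raises."""
    if table is None:
        table = metric_table(cohort, grid.values, comparator)
    return _project(
        table,
        CurveKind.PV_ROC,
        lambda m: (1.0 - m.npv, m.ppv),
        ("ppv", "npv"),
        ("1 − NPV", "PPV"),
    )


Family = Literal["SS", "PV"]


def index_roc(
    cohort: Cohort,
    grid: ThresholdGrid,
    family: Family,
    comparator: Comparator = "ge",
    table: Optional[Sequence[MetricPoint]] = None,
) -> AnnotatedCurve:
    """Index-ROC curves: J vs 1−Sp (family="SS") or PSI vs 1−NPV
    (family="PV").  Unlike plain ROC curves these may cross the diagonal;
    they carry no AUC."""
    if table is None:
        table = metric_table(cohort, grid.values, comparator)
    if family == "SS":
        return _project(
            table,
            CurveKind.SSJ_INDEX_ROC,
            lambda m: (1.0 - m.sp, m.j),
            ("j", "sp"),
            ("1 − specificity", "SS-J index (Youden)"),
        )
    if family == "PV":
        return _project(
            table,
            CurveKind.PVPSI_INDEX_ROC,
            lambda m: (1.0 - m.npv, m.psi),
            ("psi", "npv"),
            ("1 − NPV", "PV-PSI index"),
        )
    raise ValueError(f"family must be 'SS' or 'PV', got {family!r}")
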
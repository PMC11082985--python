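"""Unified SS-J / PV-PSI analysis on the cut-off axis.

The index cut-off diagram plots Youden's J and the Predictive Summary
Index PSI against the cut-off concentration on a shared axis, which makes
the two families directly comparable despite their opposite threshold
directions in ROC space.  The cut-off where the two piecewise-linear
curves cross is the *unified optimal cut-off*: the single threshold at
which sensitivity/specificity performance and predictive performance
coincide at their common maximal index value.

Also provided: reciprocal diagrams (index → persons to examine per correct
detection/prediction) and AOX summaries — the area over the x-axis of an
index curve across a cut-off range, a scalar "effectivity" summary that,
unlike the AUC, exists for predictive-value curves too.

All interpolation is piecewise-linear in the raw cut-off domain, mirroring
how values are read off a linear point plot; no extrapolation beyond the
grid span is ever performed (index curves are unstable in the sparse-count
tail, so extending them is not meaningful).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .curves import AnnotatedCurve, CurveKind, CurvePoint, ThresholdGrid
from .metrics import Cohort, Comparator, MetricPoint, metric_table, reciprocal_index

__all__ = [
    "AoxSummary",
    "IndexCutoffDiagram",
    "UnifiedResult",
    "aox",
    "index_cutoff_diagram",
    "interpolate_index",
    "max_index_point",
    "reciprocal_diagram",
    "unified_cutoff",
    "unified_min_curve",
]

#: Two curves are deemed coincident when their gap never exceeds this.
_COINCIDENT_TOL = 1e-12


@dataclass
class IndexCutoffDiagram:
    """J(c) and PSI(c) over a shared cut-off domain, with optional marked
    overlay points (e.g. a qualitative test's index at its implied cut-off)."""

    j_curve: AnnotatedCurve
    psi_curve: AnnotatedCurve
    overlays: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for curve in (self.j_curve, self.psi_curve):
            if curve.kind is CurveKind.INDEX_CUTOFF:
                ys = curve.ys
                if ys.size and (ys.min() < -1.0 - 1e-9 or ys.max() > 1.0 + 1e-9):
                    raise ValueError("index values must lie in [-1, 1]")


@dataclass(frozen=True)
class UnifiedResult:
    """Crossing of J(c) and PSI(c): the unified optimal cut-off.

    ``method`` is "crossing" when an isolated intersection was bracketed
    and bisected, "no-crossing" when the curves never meet (``cutoff_star``
    then minimises |J − PSI|), or "coincident" for identical curves.
    """

    cutoff_star: Optional[float]
    index_star: Optional[float]
    bracket: Optional[tuple[float, float]]
    all_crossings: tuple[tuple[float, float], ...]
    method: str

    def to_dict(self) -> dict:
        return {
            "cutoff_star_ug_per_L": self.cutoff_star,
            "index_star": self.index_star,
            "bracket_ug_per_L": list(self.bracket) if self.bracket else None,
            "all_crossings": [list(c) for c in self.all_crossings],
            "method": self.method,
        }


@dataclass(frozen=True)
class AoxSummary:
    """Area over the x-axis of an index curve on a cut-off range.

    ``area`` has units index × µg/L; ``normalized`` divides by the range
    width, giving a mean index level.  Negative index regions contribute 0
    by default (a test below chance adds no effectivity) — additivity over
    subranges holds either way.
    """

    family: str
    range: tuple[float, float]
    area: float
    normalized: float

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "range_ug_per_L": list(self.range),
            "area": self.area,
            "normalized": self.normalized,
        }


def index_cutoff_diagram(
    cohort: Cohort,
    grid: ThresholdGrid,
    comparator: Comparator = "ge",
    table: Optional[Sequence[MetricPoint]] = None,
) -> IndexCutoffDiagram:
    """Build the J/PSI index cut-off diagram from a cohort."""
    if table is None:
        table = metric_table(cohort, grid.values, comparator)
    j_pts, psi_pts = [], []
    j_drop, psi_drop = [], []
    for m in table:
        if m.j is None:
            j_drop.append((m.threshold, "undefined j"))
        else:
            j_pts.append(CurvePoint(cutoff=m.threshold, x=m.threshold, y=m.j, metric=m))
        if m.psi is None:
            psi_drop.append((m.threshold, "undefined psi"))
        else:
            psi_pts.append(CurvePoint(cutoff=m.threshold, x=m.threshold, y=m.psi, metric=m))
    if not j_pts:
        raise ValueError("J undefined at every threshold")
    if not psi_pts:
        raise ValueError("PSI undefined at every threshold")
    labels = ("cut-off (µg/L)", "index")
    return IndexCutoffDiagram(
        j_curve=AnnotatedCurve(CurveKind.INDEX_CUTOFF, j_pts, labels, j_drop),
        psi_curve=AnnotatedCurve(CurveKind.INDEX_CUTOFF, psi_pts, labels, psi_drop),
    )


def interpolate_index(curve: AnnotatedCurve, cutoff: float) -> float:
    """Piecewise-linear read-off of an index curve at ``cutoff``.

    Exact at grid nodes; raises outside the curve span (no extrapolation).
    """
    lo, hi = curve.span
    if not (lo <= cutoff <= hi):
        raise ValueError(
            f"cutoff {cutoff} µg/L outside curve span [{lo}, {hi}] µg/L"
        )
    return float(np.interp(cutoff, curve.cutoffs, curve.ys))


def max_index_point(curve: AnnotatedCurve) -> tuple[float, float]:
    """Grid node with the maximal index; ties break toward the lower
    cut-off (argmax returns the first maximum of the cutoff-ordered nodes)."""
    if not curve.points:
        raise ValueError("empty curve")
    i = int(np.argmax(curve.ys))
    p = curve.points[i]
    return p.cutoff, p.y


def _common_span(diagram: IndexCutoffDiagram) -> tuple[float, float]:
    j_lo, j_hi = diagram.j_curve.span
    p_lo, p_hi = diagram.psi_curve.span
    lo, hi = max(j_lo, p_lo), min(j_hi, p_hi)
    if lo > hi:
        raise ValueError("J and PSI curves have disjoint cut-off spans")
    return lo, hi


def unified_cutoff(diagram: IndexCutoffDiagram, xtol: float = 1e-6) -> UnifiedResult:
    """Locate the crossing(s) of J(c) and PSI(c).

    Every sign change of d(c) = J(c) − PSI(c) on the union of the two
    curves' nodes (restricted to the common span) is bracketed and bisected
    to ``xtol`` µg/L.  With multiple crossings the one with the greatest
    common index value is primary.  Curves that never cross yield a
    "no-crossing" result at the node grid's argmin of |d|; identical curves
    yield "coincident".
    """
    lo, hi = _common_span(diagram)
    nodes = np.union1d(diagram.j_curve.cutoffs, diagram.psi_curve.cutoffs)
    nodes = nodes[(nodes >= lo) & (nodes <= hi)]
    nodes = np.union1d(nodes, [lo, hi])

    def jf(c: float) -> float:
        return interpolate_index(diagram.j_curve, c)

    def pf(c: float) -> float:
        return interpolate_index(diagram.psi_curve, c)

    def d(c: float) -> float:
        return jf(c) - pf(c)

    dv = np.array([d(c) for c in nodes])
    if np.all(np.abs(dv) <= _COINCIDENT_TOL):
        return UnifiedResult(None, None, None, (), "coincident")

    crossings: list[tuple[float, float]] = []
    brackets: list[tuple[float, float]] = []
    for i in range(len(nodes) - 1):
        a, b = float(nodes[i]), float(nodes[i + 1])
        da, db = dv[i], dv[i + 1]
        if da == 0.0:
            if not crossings or abs(crossings[-1][0] - a) > xtol:
                crossings.append((a, jf(a)))
                brackets.append((a, b))
            continue
        if da * db < 0.0:
            root = float(brentq(d, a, b, xtol=xtol))
            crossings.append((root, jf(root)))
            brackets.append((a, b))
    if dv[-1] == 0.0 and (not crossings or abs(crossings[-1][0] - nodes[-1]) > xtol):
        crossings.append((float(nodes[-1]), jf(float(nodes[-1]))))
        brackets.append((float(nodes[-2]), float(nodes[-1])))

    if not crossings:
        i = int(np.argmin(np.abs(dv)))
        c = float(nodes[i])
        return UnifiedResult(c, jf(c), None, (), "no-crossing")

    primary = int(np.argmax([ix for _, ix in crossings]))
    c_star, i_star = crossings[primary]
    return UnifiedResult(
        cutoff_star=c_star,
        index_star=i_star,
        bracket=brackets[primary],
        all_crossings=tuple(crossings),
        method="crossing",
    )


def _clipped_polyline(
    cutoffs: np.ndarray, ys: np.ndarray, lo: float, hi: float, clip_negative: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a piecewise-linear curve to [lo, hi], inserting the interval
    endpoints and (when clipping) every zero crossing, so a single trapezoid
    pass is exact."""
    knots = set(float(c) for c in cutoffs if lo < c < hi)
    knots.update((lo, hi))
    if clip_negative:
        # roots of each linear segment become breakpoints of max(y, 0)
        for (c0, c1), (y0, y1) in zip(
            zip(cutoffs[:-1], cutoffs[1:]), zip(ys[:-1], ys[1:])
        ):
            if y0 * y1 < 0.0:
                root = c0 + (c1 - c0) * (0.0 - y0) / (y1 - y0)
                if lo < root < hi:
                    knots.add(float(root))
    xs = np.array(sorted(knots))
    vals = np.interp(xs, cutoffs, ys)
    if clip_negative:
        vals = np.maximum(vals, 0.0)
    return xs, vals


def aox(
    curve: AnnotatedCurve,
    bounds: Optional[tuple[float, float]] = None,
    clip_negative: bool = True,
    family: Optional[str] = None,
) -> AoxSummary:
    """Area over the x-axis of an index curve on ``bounds`` (default: the
    full span), by exact trapezoidal integration of the piecewise-linear
    interpolant.

    With ``clip_negative`` (default) the integrand is max(index, 0):
    below-chance regions add nothing rather than offsetting diagnostic
    value.  Additive over subranges: aox(lo, m) + aox(m, hi) = aox(lo, hi).
    """
    lo_span, hi_span = curve.span
    if bounds is None:
        lo, hi = lo_span, hi_span
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
        if lo > hi:
            raise ValueError(f"invalid range: lo {lo} > hi {hi}")
        if lo < lo_span or hi > hi_span:
            raise ValueError(
                f"range [{lo}, {hi}] outside curve span [{lo_span}, {hi_span}]"
            )
    xs, vals = _clipped_polyline(curve.cutoffs, curve.ys, lo, hi, clip_negative)
    area = float(np.trapezoid(vals, xs))
    width = hi - lo
    normalized = area / width if width > 0 else float(vals[0])
    return AoxSummary(
        family=family if family is not None else curve.kind.value,
        range=(lo, hi),
        area=area,
        normalized=normalized,
    )


def reciprocal_diagram(diagram: IndexCutoffDiagram) -> IndexCutoffDiagram:
    """Map both index curves through the reciprocal (1/index = persons to
    examine per correct detection/prediction).

    Nodes with index ≤ 0 have no person interpretation and are dropped
    (recorded on the output curves).  The reciprocal is strictly decreasing
    on positive reals, so the J/PSI crossing survives at the same cut-off.
    """
    out = []
    for curve, name in ((diagram.j_curve, "1/J"), (diagram.psi_curve, "1/PSI")):
        pts: list[CurvePoint] = []
        dropped = list(curve.dropped)
        for p in curve.points:
            rec = reciprocal_index(p.y)
            if rec is None:
                dropped.append((p.cutoff, "non-positive index"))
                continue
            pts.append(CurvePoint(cutoff=p.cutoff, x=p.cutoff, y=rec.value, metric=p.metric))
        if not pts:
            raise ValueError(f"all {name} nodes have non-positive index")
        out.append(
            AnnotatedCurve(
                CurveKind.RECIP_INDEX_CUTOFF,
                pts,
                ("cut-off (µg/L)", f"persons ({name})"),
                dropped,
            )
        )
    return IndexCutoffDiagram(
        j_curve=out[0],
        psi_curve=out[1],
        overlays=[(label, c, 1.0 / y) for (label, c, y) in diagram.overlays if y > 0],
    )


def unified_min_curve(diagram: IndexCutoffDiagram) -> AnnotatedCurve:
    """Pointwise min(J, PSI) on the union of node cut-offs over the common
    span — the integrand of the unified-min AOX (effectivity guaranteed by
    *both* index families simultaneously)."""
    lo, hi = _common_span(diagram)
    nodes = np.union1d(diagram.j_curve.cutoffs, diagram.psi_curve.cutoffs)
    nodes = np.union1d(nodes[(nodes >= lo) & (nodes <= hi)], [lo, hi])
    # crossings are breakpoints of the min; reuse the solver to include them
    res = unified_cutoff(diagram)
    nodes = np.union1d(nodes, [c for c, _ in res.all_crossings])
    pts = [
        CurvePoint(
            cutoff=float(c),
            x=float(c),
            y=min(
                interpolate_index(diagram.j_curve, float(c)),
                interpolate_index(diagram.psi_curve, float(c)),
            ),
        )
        for c in nodes
    ]
    return AnnotatedCurve(
        CurveKind.INDEX_CUTOFF, pts, ("cut-off (µg/L)", "min(J, PSI)")
    )
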
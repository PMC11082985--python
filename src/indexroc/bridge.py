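"""Bridge from a qualitative (visually read) test to the quantitative scale.

A visual lateral-flow line has no concentration read-out, only observed
(Se, Sp) or (PPV, NPV) against the gold standard.  Laying those values on
the quantitative reader's CDA curves and inverting the piecewise-linear
interpolant assigns the visual test an *implied* concentration cut-off —
the threshold at which the reader would deliver the same performance.
The reader's diagnostic gain over the visual read-out is then a simple
elementwise difference at a chosen reference cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .curves import AnnotatedCurve, CurveKind, Family, curve_by_kind
from .metrics import MetricPoint

__all__ = [
    "BridgeResult",
    "NoSolutionError",
    "QualitativeResult",
    "gain_analysis",
    "implied_cutoff",
    "invert_curve",
]

#: |y − target| below this counts as an exact node hit.
_NODE_TOL = 1e-12


class NoSolutionError(ValueError):
    """The target metric value is outside the curve's y-range (the curve is
    never extrapolated)."""


@dataclass(frozen=True)
class QualitativeResult:
    """Observed performance of a qualitative test: at least one complete
    pair, (se, sp) or (ppv, npv), must be present."""

    se: Optional[float] = None
    sp: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None
    label: str = "qualitative test"

    def __post_init__(self) -> None:
        for name in ("se", "sp", "ppv", "npv"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or not 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (self.has_ss or self.has_pv):
            raise ValueError(
                "qualitative result needs a complete (se, sp) or (ppv, npv) pair"
            )

    @property
    def has_ss(self) -> bool:
        return self.se is not None and self.sp is not None

    @property
    def has_pv(self) -> bool:
        return self.ppv is not None and self.npv is not None


@dataclass(frozen=True)
class BridgeResult:
    """Implied concentration cut-off of a qualitative test.

    ``candidates`` holds every inverse solution per metric ("se"/"sp" or
    "ppv"/"npv"); ``implied_cutoff`` combines the two metrics' solutions
    (geometric mean when they disagree — both candidates stay reported, no
    silent averaging of hidden values)."""

    implied_cutoff: float
    matched_on: Family
    candidates: dict = field(default_factory=dict)
    gains: Optional[dict] = None
    reference_cutoff: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "implied_cutoff_ug_per_L": self.implied_cutoff,
            "matched_on": self.matched_on,
            "candidates": self.candidates,
            "gains_pp": self.gains,
            "reference_cutoff_ug_per_L": self.reference_cutoff,
        }


def invert_curve(curve: AnnotatedCurve, target: float) -> list[float]:
    """All cut-offs at which the piecewise-linear curve attains ``target``.

    Exact node matches return node cut-offs (no interpolation wobble);
    otherwise every segment straddling the target contributes one linear
    solution.  Raises :class:`NoSolutionError` if the target is outside the
    curve's y-range.
    """
    cutoffs, ys = curve.cutoffs, curve.ys
    node_hits = [float(c) for c, y in zip(cutoffs, ys) if abs(y - target) <= _NODE_TOL]
    if node_hits:
        return node_hits
    sols: list[float] = []
    for i in range(len(cutoffs) - 1):
        y0, y1 = ys[i], ys[i + 1]
        if (y0 - target) * (y1 - target) < 0.0:
            frac = (target - y0) / (y1 - y0)
            sols.append(float(cutoffs[i] + frac * (cutoffs[i + 1] - cutoffs[i])))
    if not sols:
        lo, hi = ys.min(), ys.max()
        raise NoSolutionError(
            f"target {target} outside curve y-range [{lo:.4g}, {hi:.4g}] "
            "(no extrapolation)"
        )
    return sorted(sols)


_FAMILY_CURVES: dict[str, tuple[tuple[str, CurveKind], tuple[str, CurveKind]]] = {
    "SS": (("se", CurveKind.CDA_SE), ("sp", CurveKind.CDA_SP)),
    "PV": (("ppv", CurveKind.CDA_PPV), ("npv", CurveKind.CDA_NPV)),
}


def implied_cutoff(
    curve_family: Sequence[AnnotatedCurve],
    qual: QualitativeResult,
    matched_on: Family = "SS",
) -> BridgeResult:
    """Implied quantitative cut-off of a qualitative test by inverse lookup
    on the reader CDA curves.

    For the SS family the qualitative Se is inverted on the Se-vs-cutoff
    curve and Sp on the Sp curve (PPV/NPV analogously for "PV").  When the
    two metrics' representative solutions coincide — in particular, when
    both hit the same grid node exactly — that cut-off is returned as is;
    otherwise their geometric mean is returned and both candidate lists are
    reported.  With multi-solution inversions (plateaus, non-monotone
    sections) the representative pair is the one minimising the
    disagreement between the two metrics, ties toward the lower cut-off.
    """
    if matched_on not in _FAMILY_CURVES:
        raise ValueError(f"matched_on must be 'SS' or 'PV', got {matched_on!r}")
    if matched_on == "SS" and not qual.has_ss:
        raise ValueError("qualitative result lacks the (se, sp) pair")
    if matched_on == "PV" and not qual.has_pv:
        raise ValueError("qualitative result lacks the (ppv, npv) pair")

    candidates: dict[str, list[float]] = {}
    for attr, kind in _FAMILY_CURVES[matched_on]:
        curve = curve_by_kind(curve_family, kind)
        candidates[attr] = invert_curve(curve, getattr(qual, attr))
    cand_a, cand_b = candidates.values()
    reps = min(
        ((a, b) for a in cand_a for b in cand_b),
        key=lambda ab: (abs(ab[0] - ab[1]), ab[0]),
    )

    if np.isclose(reps[0], reps[1], rtol=0.0, atol=1e-9):
        combined = reps[0]
    elif reps[0] > 0 and reps[1] > 0:
        combined = float(np.sqrt(reps[0] * reps[1]))
    else:  # a zero cut-off degenerates the geometric mean
        combined = float(np.mean(reps))
    return BridgeResult(
        implied_cutoff=combined, matched_on=matched_on, candidates=candidates
    )


def gain_analysis(reader_point: MetricPoint, qual: QualitativeResult) -> dict:
    """Diagnostic gain of the quantitative reader over the visual test at a
    reference cut-off, in signed percentage points (reader − visual).

    Only metric pairs available on *both* sides are compared; if none are,
    that mismatch is an error.  A reader deficit stays negative — no
    clamping.
    """
    gains: dict[str, float] = {}
    if qual.has_ss and reader_point.se is not None and reader_point.sp is not None:
        gains["delta_se_pp"] = (reader_point.se - qual.se) * 100.0
        gains["delta_sp_pp"] = (reader_point.sp - qual.sp) * 100.0
    if qual.has_pv and reader_point.ppv is not None and reader_point.npv is not None:
        gains["delta_ppv_pp"] = (reader_point.ppv - qual.ppv) * 100.0
        gains["delta_npv_pp"] = (reader_point.npv - qual.npv) * 100.0
    if not gains:
        raise ValueError(
            "no metric pair is available on both the reader point and the "
            "qualitative result"
        )
    return gains
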
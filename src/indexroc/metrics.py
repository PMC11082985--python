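"""Single-threshold diagnostic metrics and summary indices.

Everything downstream — CDA curves, SS/PV-ROC curves, index–ROC curves,
unified cut-off diagrams — is assembled from the quantities computed here:
the confusion counts of a marker test dichotomised at a concentration
threshold, the empirical rates (sensitivity, specificity, PPV, NPV), the
Youden index J = Se + Sp − 1, the Predictive Summary Index
PSI = PPV + NPV − 1, their reciprocals (number of persons examined per
correct detection / correct prediction), and the Bayes relations tying
predictive values to (Se, Sp) at a given disease prevalence.

Conventions
-----------
* Positivity: a marker value is test-positive when it is greater than or
  equal to the threshold (``comparator="ge"``, the default, matching a
  lateral-flow line developing at or above a preset concentration).
  ``comparator="gt"`` is available.
* Undefined ratios (0/0, e.g. PPV when nobody tests positive) are returned
  as ``None`` — an explicit undefined flag — never as NaN or silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "Cohort",
    "ConfusionCounts",
    "MetricPoint",
    "Prevalence",
    "Rates",
    "Reciprocal",
    "bayes_predictive_values",
    "confusion_at_threshold",
    "metric_table",
    "prevalence_from_counts",
    "psi_index",
    "rates",
    "reciprocal_index",
    "youden_index",
]

Comparator = Literal["ge", "gt"]


@dataclass(frozen=True)
class Cohort:
    """Labelled marker measurements: one concentration (µg/L) per subject
    plus the gold-standard disease status.

    Values must be finite and non-negative.  Curve construction additionally
    requires at least one diseased and one non-diseased record.
    """

    values: np.ndarray
    diseased: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        diseased = np.asarray(self.diseased, dtype=bool)
        if values.ndim != 1 or diseased.ndim != 1:
            raise ValueError("values and diseased must be one-dimensional")
        if values.shape != diseased.shape:
            raise ValueError(
                f"values ({values.size}) and diseased ({diseased.size}) "
                "must have equal length"
            )
        if values.size == 0:
            raise ValueError("empty cohort")
        if not np.all(np.isfinite(values)):
            raise ValueError("marker values must be finite")
        if np.any(values < 0):
            raise ValueError("marker values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "diseased", diseased)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, bool]], meta: str = ""
    ) -> "Cohort":
        """Build from ``(value, diseased)`` pairs."""
        recs = list(records)
        if not recs:
            raise ValueError("empty cohort")
        values = np.array([r[0] for r in recs], dtype=float)
        diseased = np.array([bool(r[1]) for r in recs])
        return cls(values=values, diseased=diseased, meta=meta)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_diseased(self) -> int:
        return int(np.count_nonzero(self.diseased))

    @property
    def n_nondiseased(self) -> int:
        return len(self) - self.n_diseased

    @property
    def prevalence(self) -> "Prevalence":
        return prevalence_from_counts(self.n_diseased, self.n_nondiseased)

    def require_both_classes(self) -> None:
        if self.n_diseased == 0 or self.n_nondiseased == 0:
            raise ValueError(
                "curve construction requires at least one diseased and one "
                "non-diseased record"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN of a dichotomised test at one threshold (µg/L)."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


class Rates(NamedTuple):
    """Empirical rates from a confusion matrix; ``None`` marks 0/0."""

    se: Optional[float]
    sp: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


class Reciprocal(NamedTuple):
    """Reciprocal of a summary index: ``value`` is the raw real (persons to
    examine per one correct detection/prediction), ``persons`` the nearest
    whole-person count."""

    value: float
    persons: int


@dataclass(frozen=True)
class Prevalence:
    """Disease prevalence, optionally carrying the counts it came from."""

    p: float
    n_diseased: Optional[int] = None
    n_total: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0) or not math.isfinite(self.p):
            raise ValueError(f"prevalence must lie in [0, 1], got {self.p}")


def prevalence_from_counts(n_diseased: int, n_nondiseased: int) -> Prevalence:
    """Prevalence from class counts, e.g. 91 diseased / 1152 non-diseased
    gives p = 91/1243 ≈ 0.073."""
    if n_diseased < 0 or n_nondiseased < 0:
        raise ValueError("counts must be non-negative")
    total = n_diseased + n_nondiseased
    if total == 0:
        raise ValueError("total count must be positive")
    return Prevalence(p=n_diseased / total, n_diseased=n_diseased, n_total=total)


def confusion_at_threshold(
    cohort: Cohort, threshold: float, comparator: Comparator = "ge"
) -> ConfusionCounts:
    """Dichotomise the cohort at ``threshold`` and count the confusion cells.

    A record is test-positive iff its value is ``>= threshold`` ("ge", the
    default) or ``> threshold`` ("gt").  Totals conserve the cohort sizes:
    tp+fn equals the number diseased, fp+tn the number non-diseased.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if comparator == "ge":
        positive = cohort.values >= threshold
    elif comparator == "gt":
        positive = cohort.values > threshold
    else:
        raise ValueError(f"comparator must be 'ge' or 'gt', got {comparator!r}")
    d = cohort.diseased
    return ConfusionCounts(
        tp=int(np.count_nonzero(positive & d)),
        fp=int(np.count_nonzero(positive & ~d)),
        tn=int(np.count_nonzero(~positive & ~d)),
        fn=int(np.count_nonzero(~positive & d)),
        threshold=float(threshold),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def rates(counts: ConfusionCounts) -> Rates:
    """Sensitivity, specificity, PPV and NPV from confusion counts.

    Any cell with an empty denominator (0/0) yields ``None`` rather than a
    number — the small-count regime at high thresholds makes this a routine
    occurrence, not an error.
    """
    return Rates(
        se=_ratio(counts.tp, counts.tp + counts.fn),
        sp=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def youden_index(se: float, sp: float) -> float:
    """Youden's J = Se + Sp − 1 (the SS summary index).

    Ranges over [−1, 1]; 0 on the chance diagonal (Se = 1 − Sp), 1 for a
    perfect test.
    """
    _check_proportion("sensitivity", se)
    _check_proportion("specificity", sp)
    return se + sp - 1.0


def psi_index(ppv: float, npv: float) -> float:
    """Predictive Summary Index PSI = PPV + NPV − 1, the predictive-value
    analogue of Youden's J.  Prevalence-dependent through PPV and NPV."""
    _check_proportion("PPV", ppv)
    _check_proportion("NPV", npv)
    return ppv + npv - 1.0


def reciprocal_index(index: Optional[float]) -> Optional[Reciprocal]:
    """1/J (or 1/PSI): how many persons must be examined to correctly detect
    (or predict) one case.  Undefined (``None``) for index ≤ 0 — a test at or
    below chance detects nobody per examination in this accounting."""
    if index is None or index <= 0.0:
        return None
    value = 1.0 / index
    return Reciprocal(value=value, persons=int(round(value)))


def bayes_predictive_values(
    se: float, sp: float, prev: Prevalence | float
) -> tuple[Optional[float], Optional[float]]:
    """PPV and NPV implied by (Se, Sp) at prevalence p via Bayes' theorem:

        PPV = Se·p / (Se·p + (1−Sp)(1−p))
        NPV = Sp(1−p) / (Sp(1−p) + (1−Se)p)

    Prevalence must be strictly inside (0, 1).  A 0/0 (e.g. Se = 0 and
    Sp = 1) yields ``None`` for the affected value.
    """
    _check_proportion("sensitivity", se)
    _check_proportion("specificity", sp)
    p = prev.p if isinstance(prev, Prevalence) else float(prev)
    if not (0.0 < p < 1.0):
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {p}")
    ppv_den = se * p + (1.0 - sp) * (1.0 - p)
    npv_den = sp * (1.0 - p) + (1.0 - se) * p
    ppv = None if ppv_den == 0.0 else se * p / ppv_den
    npv = None if npv_den == 0.0 else sp * (1.0 - p) / npv_den
    return ppv, npv


@dataclass(frozen=True)
class MetricPoint:
    """Per-threshold bundle: counts, rates, indices and reciprocals.

    Fields that are undefined at this threshold (empty denominator, index
    ≤ 0 for a reciprocal) hold ``None``.
    """

    threshold: float
    se: Optional[float]
    sp: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    j: Optional[float]
    psi: Optional[float]
    recip_j: Optional[Reciprocal]
    recip_psi: Optional[Reciprocal]
    counts: ConfusionCounts = field(repr=False)

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "MetricPoint":
        r = rates(counts)
        j = None if r.se is None or r.sp is None else youden_index(r.se, r.sp)
        psi = None if r.ppv is None or r.npv is None else psi_index(r.ppv, r.npv)
        return cls(
            threshold=counts.threshold,
            se=r.se,
            sp=r.sp,
            ppv=r.ppv,
            npv=r.npv,
            j=j,
            psi=psi,
            recip_j=reciprocal_index(j),
            recip_psi=reciprocal_index(psi),
            counts=counts,
        )

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, threshold: float, comparator: Comparator = "ge"
    ) -> "MetricPoint":
        return cls.from_counts(confusion_at_threshold(cohort, threshold, comparator))

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "se": self.se,
            "sp": self.sp,
            "ppv": self.ppv,
            "npv": self.npv,
            "j": self.j,
            "psi": self.psi,
            "recip_j": None if self.recip_j is None else self.recip_j.value,
            "recip_j_persons": None if self.recip_j is None else self.recip_j.persons,
            "recip_psi": None if self.recip_psi is None else self.recip_psi.value,
            "recip_psi_persons": (
                None if self.recip_psi is None else self.recip_psi.persons
            ),
        }
        d.update(
            {k: v for k, v in self.counts.to_dict().items() if k != "threshold"}
        )
        return d


def metric_table(
    cohort: Cohort,
    thresholds: Sequence[float],
    comparator: Comparator = "ge",
) -> list[MetricPoint]:
    """Evaluate :class:`MetricPoint` at every threshold of a grid."""
    cohort.require_both_classes()
    return [MetricPoint.from_cohort(cohort, t, comparator) for t in thresholds]
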
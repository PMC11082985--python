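"""Synthetic cohorts and the worked-example summary table.

Real tumour-marker concentrations are heavily right-skewed with a broad
overlap between diseased and disease-free groups, observed above a hard
detection floor, at low disease prevalence.  :func:`generate_cohort`
emulates exactly that: two log-normal marker mixtures clipped at the
reader's detection limit (0.5 µg/L), with class sizes fixed by the spec so
the empirical prevalence is exact, and a pinned PRNG (NumPy PCG64 via
``default_rng``) so every cohort is reproducible from its seed.

The default parameters follow the bladder-cancer study regime this package
uses as its worked example: 91 diseased vs 1152 disease-free subjects
(prevalence 0.073) and a diseased distribution whose sensitivity sweeps
from ≈0.9 down to ≈0.1 across the preset grid 5–300 µg/L.

:func:`worked_example_table` carries the published per-cutoff summary
values of that study (the raw patient-level data are not public), so curve
and diagram code can be driven from printed numbers alone.  Entries whose
printed values are mutually inconsistent are flagged, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import Cohort

__all__ = [
    "CohortSpec",
    "LogNormalParams",
    "generate_cohort",
    "group_se_sp",
    "worked_example_table",
]


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal marker distribution: ``mu``/``sigma`` on the ln scale
    (µg/L units after exponentiation)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def sf(self, x: float | np.ndarray) -> float | np.ndarray:
        """P(X ≥ x): survival function of the un-clipped distribution."""
        return stats.lognorm.sf(x, s=self.sigma, scale=math.exp(self.mu))


# Defaults solve Se(5 µg/L) ≈ 0.9 and Se(300 µg/L) ≈ 0.1 for the diseased
# group, and put Sp(7.5) ≈ 0.64 / Sp(10) ≈ 0.77 for the disease-free group —
# the regime of the worked example's printed reader values.
DEFAULT_DISEASED = LogNormalParams(mu=3.66, sigma=1.60)
DEFAULT_NONDISEASED = LogNormalParams(mu=1.80, sigma=0.80)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible synthetic cohort."""

    n_diseased: int = 91
    n_nondiseased: int = 1152
    diseased_dist: LogNormalParams = field(default=DEFAULT_DISEASED)
    nondiseased_dist: LogNormalParams = field(default=DEFAULT_NONDISEASED)
    detection_floor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseased < 0 or self.n_nondiseased < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_diseased + self.n_nondiseased == 0:
            raise ValueError("cohort must contain at least one record")
        if self.detection_floor < 0 or not math.isfinite(self.detection_floor):
            raise ValueError("detection floor must be finite and non-negative")

    def to_dict(self) -> dict:
        return {
            "n_diseased": self.n_diseased,
            "n_nondiseased": self.n_nondiseased,
            "diseased_dist": {"mu": self.diseased_dist.mu, "sigma": self.diseased_dist.sigma},
            "nondiseased_dist": {
                "mu": self.nondiseased_dist.mu,
                "sigma": self.nondiseased_dist.sigma,
            },
            "detection_floor": self.detection_floor,
            "seed": self.seed,
        }


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from the spec's two log-normal groups.

    Values below the detection floor are clipped up to the floor (a reader
    cannot report below its detection limit).  Empirical prevalence equals
    n_diseased / (n_diseased + n_nondiseased) exactly, and the same seed
    always yields the same cohort.
    """
    rng = np.random.default_rng(spec.seed)
    d = rng.lognormal(spec.diseased_dist.mu, spec.diseased_dist.sigma, spec.n_diseased)
    h = rng.lognormal(
        spec.nondiseased_dist.mu, spec.nondiseased_dist.sigma, spec.n_nondiseased
    )
    values = np.maximum(np.concatenate([d, h]), spec.detection_floor)
    diseased = np.concatenate(
        [np.ones(spec.n_diseased, dtype=bool), np.zeros(spec.n_nondiseased, dtype=bool)]
    )
    return Cohort(values=values, diseased=diseased, meta=f"synthetic seed={spec.seed}")


def group_se_sp(spec: CohortSpec, threshold: float) -> tuple[float, float]:
    """Closed-form (Se, Sp) of the generating distributions at a threshold
    (≥-positivity).  The detection-floor clip is immaterial for thresholds
    above the floor.  This is the population truth the empirical curves
    fluctuate around."""
    se = float(spec.diseased_dist.sf(threshold))
    sp = float(1.0 - spec.nondiseased_dist.sf(threshold))
    return se, sp


def worked_example_table() -> pd.DataFrame:
    """Published per-cutoff summary values of the bladder-cancer worked
    example (prevalence 0.073; 91 diseased / 1152 disease-free).

    Columns: source ("reader" photometric / "visual" qualitative), cutoff
    in µg/L, whichever of se/sp/ppv/npv/j/psi/tp/fp were printed, and a
    ``consistent`` flag.  The reader's 250 µg/L predictive-value row is
    flagged False: its printed PSI (0.459) does not equal PPV + NPV − 1
    for the printed PPV 0.5 / NPV 0.928 (= 0.428), and the printed
    TP=8 / FP=7 give PPV 8/15 ≈ 0.533, not 0.5.  The flag marks the
    discrepancy; nothing is corrected.
    """
    rows = [
        # reader, SS family
        dict(source="reader", cutoff=10.0, se=0.66, sp=0.765, j=0.425, consistent=True),
        # reader, PV family (internally inconsistent as printed)
        dict(
            source="reader",
            cutoff=250.0,
            ppv=0.5,
            npv=0.928,
            psi=0.459,
            tp=8,
            fp=7,
            consistent=False,
        ),
        dict(source="reader", cutoff=300.0, tp=6, fp=6, consistent=True),
        # visual qualitative test
        dict(source="visual", cutoff=7.5, se=0.659, sp=0.633, consistent=True),
        dict(source="visual", cutoff=12.5, ppv=0.124, npv=0.959, consistent=True),
        dict(source="visual", cutoff=35.0, j=0.328, consistent=True),
        dict(source="visual", cutoff=5.4, psi=0.083, consistent=True),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "source",
            "cutoff",
            "se",
            "sp",
            "ppv",
            "npv",
            "j",
            "psi",
            "tp",
            "fp",
            "consistent",
        ],
    )
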
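"""PA/Ao ratio statistics: outlier capping, cohort standard value, grouping.

The screening biometric is the ratio of the pulmonary-artery diameter to the
ascending-aorta diameter in the three-vessel view.  A cohort of normal-case
ratios defines the *standard value* — mean +/- 2 SD — and cases are grouped as
``low`` (below the band), ``normal`` (within it, boundaries inclusive) or
``high`` (above it).  Ratios above a cap (3.5 by default) are treated as
outliers and clipped before any statistic is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCohortWarning, InsufficientData, InvalidDiameter

GROUPS = ("low", "normal", "high")
COHORT_LABELS = ("normal", "CHD")

#: default outlier cap on the PA/Ao ratio
RATIO_CAP = 3.5


@dataclass(frozen=True)
class StandardRange:
    """Cohort mean and 2SD half-width defining the normal band."""

    mean: float
    half_width_2sd: float
    n_cases: int = 0

    def __post_init__(self):
        if self.half_width_2sd < 0:
            raise ValueError("half_width_2sd must be >= 0")

    @property
    def lower(self) -> float:
        return self.mean - self.half_width_2sd

    @property
    def upper(self) -> float:
        return self.mean + self.half_width_2sd

    @property
    def sd(self) -> float:
        return self.half_width_2sd / 2.0


#: bundled normal-cohort standard value (config data, not recomputed):
#: PA/Ao = 1.237 +/- 0.364 (mean +/- 2SD) from 270 normal cases
DEFAULT_STANDARD_RANGE = StandardRange(mean=1.237, half_width_2sd=0.364, n_cases=270)


@dataclass
class RatioRecord:
    """One measured (or simulated) case: diameters, ratio, screening group."""

    case_id: str
    frame_id: str
    cohort_label: str  # "normal" or "CHD"
    pa_px: float
    ao_px: float
    ratio: float
    clipped: bool = False
    group: Optional[str] = None  # "low" / "normal" / "high" once classified

    def classified(self, rng: StandardRange) -> "RatioRecord":
        return replace(self, group=classify_ratio(self.ratio, rng))


def compute_ratio(pa_px: float, ao_px: float) -> float:
    """PA/Ao ratio from the two diameters (pixels; the unit cancels)."""
    if pa_px <= 0 or ao_px <= 0:
        raise InvalidDiameter(f"diameters must be positive, got PA={pa_px}, Ao={ao_px}")
    return pa_px / ao_px


def clip_ratio(ratio: float, cap: float = RATIO_CAP) -> tuple[float, bool]:
    """Cap outlier ratios; returns (value, clipped flag)."""
    if ratio <= 0:
        raise InvalidDiameter(f"ratio must be positive, got {ratio}")
    if ratio > cap:
        return cap, True
    return float(ratio), False


def compute_standard_range(ratios: Sequence[float]) -> StandardRange:
    """Mean +/- 2 sample SD (n-1 denominator) of a cohort of ratios."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size < 2:
        raise InsufficientData("standard range needs at least 2 ratios")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        warnings.warn(
            "cohort has zero ratio spread; the normal band collapses to a point",
            DegenerateCohortWarning,
        )
    return StandardRange(mean=mean, half_width_2sd=2.0 * sd, n_cases=int(arr.size))


def classify_ratio(ratio: float, rng: StandardRange) -> str:
    """Place a (clipped) ratio in the low / normal / high screening group.

    Boundary values exactly at mean +/- 2SD count as normal.
    """
    if ratio < rng.lower:
        return "low"
    if ratio > rng.upper:
        return "high"
    return "normal"


def group_summary(records: Iterable[RatioRecord]) -> pd.DataFrame:
    """Per cohort-label x group counts and ratio mean +/- sample SD.

    Layout mirrors the usual reporting table: the normal cohort in one row
    block, CHD cases split into low/normal/high.  Empty cells keep n=0 with
    absent (NaN) statistics.
    """
    rows = []
    recs = list(records)
    for rec in recs:
        if rec.group is None:
            raise ValueError(f"record {rec.case_id} has not been classified")
    for label in COHORT_LABELS:
        for group in GROUPS:
            vals = [r.ratio for r in recs if r.cohort_label == label and r.group == group]
            rows.append(
                {
                    "cohort_label": label,
                    "group": group,
                    "n": len(vals),
                    "mean_ratio": float(np.mean(vals)) if vals else np.nan,
                    "sd_ratio": float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["cohort_label", "group"])
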
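"""Segmentation and screening evaluation: Dice/mDice, deviation score, ROC/AUC.

Segmentation quality is the per-class Dice coefficient 2TP/(2TP+FP+FN) and
its per-frame mean over evaluable classes (mDice).  Screening performance
uses a deviation score |ratio - cohort mean|, so that both abnormally low and
abnormally high PA/Ao ratios score as abnormal, and standard ROC analysis
with CHD as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from . import cohort as _cohort
from .cohort import StandardRange
from .errors import EmptyInput, ShapeMismatch, SingleClass, UndefinedDice
from .geometry import CLASS_NAMES, VESSEL_CLASSES, as_mask

POSITIVE_LABEL = "CHD"


@dataclass(frozen=True)
class DiceReport:
    """Per-class Dice values and their per-frame mean."""

    per_class: Mapping[int, float]
    mdice: float
    n_classes_evaluated: int


@dataclass(frozen=True)
class ROCResult:
    """ROC curve (descending thresholds) and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def dice(gt, pred, class_code: int) -> float:
    """Dice overlap 2TP/(2TP+FP+FN) of one class between two masks."""
    g = as_mask(gt).grid
    p = as_mask(pred).grid
    if g.shape != p.shape:
        raise ShapeMismatch(f"mask shapes differ: {g.shape} vs {p.shape}")
    gm = g == class_code
    pm = p == class_code
    tp = int(np.count_nonzero(gm & pm))
    fp = int(np.count_nonzero(~gm & pm))
    fn = int(np.count_nonzero(gm & ~pm))
    if tp + fp + fn == 0:
        raise UndefinedDice(
            f"class {CLASS_NAMES.get(class_code, class_code)} absent from both masks"
        )
    return 2.0 * tp / (2.0 * tp + fp + fn)


def mdice_frame(
    gt,
    pred,
    classes: Sequence[int] = VESSEL_CLASSES,
    absent_as_one: bool = False,
) -> DiceReport:
    """Mean Dice over the vessel classes of one frame.

    A class absent from both masks has an undefined (0/0) Dice and is excluded
    from the mean by default; set ``absent_as_one`` to score it as 1 instead.
    """
    per_class: dict[int, float] = {}
    for code in classes:
        try:
            per_class[code] = dice(gt, pred, code)
        except UndefinedDice:
            if absent_as_one:
                per_class[code] = 1.0
    if not per_class:
        raise UndefinedDice("no class evaluable in either mask")
    values = list(per_class.values())
    return DiceReport(
        per_class=per_class,
        mdice=float(np.mean(values)),
        n_classes_evaluated=len(values),
    )


def screening_score(ratio: float, rng: StandardRange) -> float:
    """Deviation score |ratio - cohort mean|; larger means more abnormal.

    The absolute deviation folds low- and high-ratio abnormalities onto one
    scale so a single ROC sweep captures both tails.
    """
    return abs(ratio - rng.mean)


def _as_binary(labels: Sequence) -> np.ndarray:
    return np.asarray([1 if lab == POSITIVE_LABEL or lab is True or lab == 1 else 0
                       for lab in labels])


def roc_auc(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """ROC curve and trapezoidal AUC with CHD as the positive class.

    Thresholds sweep the unique scores in descending order; tied scores share
    one threshold, so the trapezoidal area equals the Mann-Whitney statistic
    with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(scores) != len(y):
        raise ValueError("scores and labels must have equal length")
    if y.min() == y.max():
        raise SingleClass("ROC needs both normal and CHD labels")
    fpr, tpr, thresholds = _roc_curve(y, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


def mean_auc(aucs: Sequence[float]) -> float:
    """Arithmetic mean of per-rater (or per-method) AUC values."""
    aucs = list(aucs)
    if not aucs:
        raise EmptyInput("mean_auc of an empty list")
    return float(np.mean(aucs))


def rater_evaluation(
    measurements: pd.DataFrame,
    rng: StandardRange = _cohort.DEFAULT_STANDARD_RANGE,
    cap: float = _cohort.RATIO_CAP,
) -> dict:
    """Per-rater and per-skill-group screening AUCs from manual measurements.

    ``measurements`` needs columns rater_id, skill_group, case_id, label,
    pa_px, ao_px.  Each rater's diameters become capped ratios, then deviation
    scores, then one ROC AUC per rater; skill groups report the arithmetic
    mean of their raters' AUCs.  Returns a dict with ``per_rater`` (DataFrame),
    ``per_group`` (group -> mean AUC) and ``overall_mean_auc``.
    """
    required = {"rater_id", "skill_group", "case_id", "label", "pa_px", "ao_px"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for rater_id, df in measurements.groupby("rater_id", sort=True):
        ratios = [
            _cohort.clip_ratio(_cohort.compute_ratio(pa, ao), cap=cap)[0]
            for pa, ao in zip(df["pa_px"], df["ao_px"])
        ]
        scores = [screening_score(r, rng) for r in ratios]
        result = roc_auc(scores, list(df["label"]))
        rows.append(
            {
                "rater_id": rater_id,
                "skill_group": df["skill_group"].iloc[0],
                "n_cases": len(df),
                "auc": result.auc,
            }
        )
    per_rater = pd.DataFrame(rows)
    per_group = {
        group: mean_auc(list(sub["auc"]))
        for group, sub in per_rater.groupby("skill_group", sort=True)
    }
    return {
        "per_rater": per_rater,
        "per_group": per_group,
        "overall_mean_auc": mean_auc(list(per_rater["auc"])),
    }
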
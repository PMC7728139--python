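"""Accuracy and precision statistics for FSA prediction and FSP classification.

Prediction models are scored with MSE, RMSE, MAE and MAPE, and their
agreement with the ground truth is summarized Bland-Altman style: the bias is
the mean difference (true minus predicted FSA), the 95% limits of agreement
are bias +/- 1.96 SD of the differences, and the "maximum precision" is the
width between the limits.

Classification models are scored from a 3x3 confusion matrix with rows/
columns in the fixed order RF, MF, FF:

    accuracy  = total correct / total sample * 100%
    recall    = true positives of a true class / total sample of that true class * 100%
    precision = true positives of an estimated class / total sample of that estimated class * 100%

Report rounding is half-away-from-zero to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import FSP_CLASSES

__all__ = [
    "PredictionErrorReport",
    "BlandAltmanReport",
    "ConfusionMatrix3",
    "prediction_metrics",
    "bland_altman",
    "confusion",
    "matrix_metrics",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the published tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class PredictionErrorReport:
    mse: float   # deg^2
    rmse: float  # deg
    mae: float   # deg
    mape: float  # unitless fraction
    n: int
    n_mape_excluded: int = 0


@dataclass(frozen=True)
class BlandAltmanReport:
    bias: float        # deg, mean(true - predicted)
    loa_lower: float   # deg
    loa_upper: float   # deg
    max_precision: float  # deg, loa_upper - loa_lower
    sd_diff: float
    n: int


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 true-vs-estimated counts, rows and columns ordered RF, MF, FF."""

    counts: np.ndarray
    classes: tuple[str, ...] = FSP_CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (3, 3) or np.any(counts < 0):
            raise InputError("confusion matrix must be 3x3 with nonnegative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def _paired(true, pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise InputError("true/pred must be equal-length nonempty 1-D arrays")
    return t, p


def prediction_metrics(true, pred) -> PredictionErrorReport:
    """MSE, RMSE, MAE, MAPE of predicted vs true FSA.

    MAPE is mean(|true - pred| / |true|) over records with true != 0; exact
    zero-angle records are excluded from MAPE only and counted in the report.
    """
    t, p = _paired(true, pred)
    err = t - p
    mse = float(np.mean(err**2))
    nonzero = t != 0
    n_excl = int(np.sum(~nonzero))
    if not np.any(nonzero):
        raise InputError("MAPE undefined: all true angles are zero")
    mape = float(np.mean(np.abs(err[nonzero] / t[nonzero])))
    return PredictionErrorReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(err))),
        mape=mape,
        n=t.size,
        n_mape_excluded=n_excl,
    )


def bland_altman(true, pred) -> BlandAltmanReport:
    """95% limits of agreement of (true - predicted) FSA differences."""
    t, p = _paired(true, pred)
    if t.size < 2:
        raise InputError("Bland-Altman needs at least 2 pairs")
    diff = t - p
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    half = 1.96 * sd
    return BlandAltmanReport(
        bias=bias,
        loa_lower=bias - half,
        loa_upper=bias + half,
        max_precision=2 * half,
        sd_diff=sd,
        n=t.size,
    )


def confusion(true_classes, pred_classes) -> ConfusionMatrix3:
    """Count true-vs-estimated FSP classes into the fixed RF/MF/FF layout."""
    t = np.asarray(true_classes, dtype=object)
    p = np.asarray(pred_classes, dtype=object)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise InputError("class arrays must be equal-length nonempty 1-D")
    lut = {c: i for i, c in enumerate(FSP_CLASSES)}
    counts = np.zeros((3, 3), dtype=int)
    for a, b in zip(t, p):
        try:
            counts[lut[a], lut[b]] += 1
        except KeyError as exc:
            raise InputError(f"unknown class label {exc.args[0]!r}") from None
    return ConfusionMatrix3(counts)


def matrix_metrics(cm: ConfusionMatrix3) -> dict:
    """Accuracy, per-class recall and per-class precision (percent).

    Precision of a class nobody was assigned to is undefined and reported as
    NaN.  ``*_rounded`` entries use the one-decimal report convention.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise InputError("empty confusion matrix")
    correct = np.trace(counts)
    accuracy = 100.0 * correct / total
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    diag = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, 100.0 * diag / row_sums, np.nan)
        precision = np.where(col_sums > 0, 100.0 * diag / col_sums, np.nan)
    out = {
        "accuracy": float(accuracy),
        "recall": dict(zip(cm.classes, map(float, recall))),
        "precision": dict(zip(cm.classes, map(float, precision))),
    }
    out["accuracy_rounded"] = round_half_away(out["accuracy"])
    out["recall_rounded"] = {
        c: (round_half_away(v) if np.isfinite(v) else float("nan"))
        for c, v in out["recall"].items()
    }
    out["precision_rounded"] = {
        c: (round_half_away(v) if np.isfinite(v) else float("nan"))
        for c, v in out["precision"].items()
    }
    return out
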
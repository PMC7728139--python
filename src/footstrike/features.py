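"""The ten stance-phase predictors extracted from a fore/aft insole trace.

All predictors are relative quantities, which makes them dimensionless and
invariant to overall force scale (runner mass, calibration gain):

================  ==============================================================
ir_fore/ir_aft    sensor impulse / total impulse over the whole stance (0-100%)
ir_*_0_33         the same ratio over the first third of stance (IC to 33%)
pf_fore/pf_aft    sensor peak force / total peak force over the stance
rfd_fore/rfd_aft  sensor peak loading rate / total peak loading rate
ln_pct_rfd_*      natural log of WHERE the sensor's peak loading rate occurs,
                  expressed as a percent of stance (IC = 0%, TO = 100%)
================  ==============================================================

Ratios are stored as fractions in [0, 1] (the log-timing variables use the
0-100 percent scale inside the log); this convention is the one under which
the published fixed-coefficient regression reproduces the per-class mean FSA.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStanceError, InputError
from .events import StanceWindow
from .simulate import ForceTrace

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureVector",
    "NormalityReport",
    "impulse",
    "extract_features",
    "normality_screen",
]

#: Column order of every feature table produced by this package.
FEATURE_COLUMNS = (
    "ir_fore",
    "ir_aft",
    "ir_fore_0_33",
    "ir_aft_0_33",
    "pf_fore",
    "pf_aft",
    "rfd_fore",
    "rfd_aft",
    "ln_pct_rfd_fore",
    "ln_pct_rfd_aft",
)


@dataclass(frozen=True)
class FeatureVector:
    """The ten predictors for one step."""

    ir_fore: float
    ir_aft: float
    ir_fore_0_33: float
    ir_aft_0_33: float
    pf_fore: float
    pf_aft: float
    rfd_fore: float
    rfd_aft: float
    ln_pct_rfd_fore: float
    ln_pct_rfd_aft: float

    def __post_init__(self) -> None:
        if abs(self.ir_fore + self.ir_aft - 1.0) > 1e-9:
            raise InputError("ir_fore + ir_aft must equal 1")
        if abs(self.ir_fore_0_33 + self.ir_aft_0_33 - 1.0) > 1e-9:
            raise InputError("ir_fore_0_33 + ir_aft_0_33 must equal 1")
        for name in ("ir_fore", "ir_aft", "ir_fore_0_33", "ir_aft_0_33",
                     "pf_fore", "pf_aft"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.rfd_fore < 0 or self.rfd_aft < 0:
            raise InputError("RFD ratios must be >= 0")
        if not (np.isfinite(self.ln_pct_rfd_fore) and np.isfinite(self.ln_pct_rfd_aft)):
            raise InputError("log timing features must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class NormalityReport:
    """Standardized skewness/kurtosis screen for a feature table.

    A variable fails the screen (and is a log-transform candidate) when either
    standardized moment exceeds 2.58 in absolute value, the two-sided z
    critical value at alpha = 0.01.
    """

    skew_z: pd.Series
    kurtosis_z: pd.Series
    transform_flags: pd.Series

    @property
    def flagged(self) -> list[str]:
        return list(self.transform_flags.index[self.transform_flags])


def _sensor_signal(trace: ForceTrace, sensor: str) -> np.ndarray:
    try:
        return {
            "fore": trace.force_fore,
            "aft": trace.force_aft,
            "total": trace.force_total,
        }[sensor]
    except KeyError:
        raise InputError(f"unknown sensor {sensor!r}") from None


def impulse(trace: ForceTrace, window: StanceWindow, sensor: str = "total") -> float:
    """Trapezoidal force-time integral (N*s) of one sensor over a window."""
    if window.to_index >= len(trace):
        raise InputError("window extends beyond the trace")
    sl = slice(window.ic_index, window.to_index + 1)
    y = _sensor_signal(trace, sensor)[sl]
    t = trace.time[sl]
    if y.size < 2:
        raise InputError("window must span at least 2 samples")
    return float(np.trapezoid(y, t))


def _first_third(window: StanceWindow) -> StanceWindow:
    # "IC to 33%" with frame rounding: IC .. IC + round((TO-IC)/3), inclusive
    span = window.to_index - window.ic_index
    return StanceWindow(window.ic_index, window.ic_index + max(int(round(span / 3)), 1))


def _peak_rate(force: np.ndarray, window: StanceWindow, fs: float) -> tuple[float, int]:
    """Max backward-difference loading rate within the window and its index.

    Rates are defined for frames ic+1 .. to (each needs a predecessor inside
    the window).  First index wins ties.
    """
    seg = force[window.ic_index : window.to_index + 1]
    rates = np.diff(seg) * fs
    k = int(np.argmax(rates))
    return float(rates[k]), window.ic_index + 1 + k


def extract_features(trace: ForceTrace, window: StanceWindow) -> FeatureVector:
    """Compute the ten predictors for one stance-delimited step."""
    if window.to_index >= len(trace):
        raise InputError("window extends beyond the trace")
    if window.n_samples < 4:
        raise DegenerateStanceError("stance window too short for feature extraction")

    total_impulse = impulse(trace, window, "total")
    if total_impulse <= 0:
        raise DegenerateStanceError("zero total impulse in stance window")
    ir_fore = impulse(trace, window, "fore") / total_impulse
    ir_aft = 1.0 - ir_fore

    third = _first_third(window)
    third_total = impulse(trace, third, "total")
    if third_total <= 0:
        raise DegenerateStanceError("zero total impulse in first third of stance")
    ir_fore_33 = impulse(trace, third, "fore") / third_total
    ir_aft_33 = 1.0 - ir_fore_33

    sl = slice(window.ic_index, window.to_index + 1)
    peak_total = float(np.max(trace.force_total[sl]))
    pf_fore = float(np.max(trace.force_fore[sl])) / peak_total
    pf_aft = float(np.max(trace.force_aft[sl])) / peak_total

    fs = trace.sampling_rate
    total_rate, _ = _peak_rate(trace.force_total, window, fs)
    if total_rate <= 0:
        raise DegenerateStanceError("nonpositive peak total loading rate")
    fore_rate, fore_idx = _peak_rate(trace.force_fore, window, fs)
    aft_rate, aft_idx = _peak_rate(trace.force_aft, window, fs)
    rfd_fore = max(fore_rate, 0.0) / total_rate
    rfd_aft = max(aft_rate, 0.0) / total_rate

    span = window.to_index - window.ic_index
    pct_fore = 100.0 * (fore_idx - window.ic_index) / span
    pct_aft = 100.0 * (aft_idx - window.ic_index) / span
    if pct_fore <= 0 or pct_aft <= 0:
        raise DegenerateStanceError("peak RFD at IC exactly: log timing undefined")

    return FeatureVector(
        ir_fore=ir_fore,
        ir_aft=ir_aft,
        ir_fore_0_33=ir_fore_33,
        ir_aft_0_33=ir_aft_33,
        pf_fore=pf_fore,
        pf_aft=pf_aft,
        rfd_fore=rfd_fore,
        rfd_aft=rfd_aft,
        ln_pct_rfd_fore=float(np.log(pct_fore)),
        ln_pct_rfd_aft=float(np.log(pct_aft)),
    )


def normality_screen(
    feature_table: pd.DataFrame,
    columns: tuple[str, ...] = FEATURE_COLUMNS,
    critical: float = 2.58,
) -> NormalityReport:
    """Standardized skewness/kurtosis screen per variable.

    The statistics are the bias-corrected sample moments divided by their
    standard errors under normality (the z statistics SPSS prints); 2.58 is
    the two-sided 1% critical value.  Constant columns have undefined moments
    and are flagged.
    """
    present = [c for c in columns if c in feature_table.columns]
    if not present:
        raise InputError("no screened columns present in the feature table")
    n = len(feature_table)
    if n < 8:
        raise InputError("normality screen needs at least 8 rows")

    se_skew = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    se_kurt = 2.0 * se_skew * np.sqrt((n * n - 1.0) / ((n - 3) * (n + 5)))

    skew_z, kurt_z, flags = {}, {}, {}
    for col in present:
        x = feature_table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skew_z[col] = np.nan
            kurt_z[col] = np.nan
            flags[col] = True  # constant: moments undefined, flag for attention
            continue
        skew_z[col] = stats.skew(x, bias=False) / se_skew
        kurt_z[col] = stats.kurtosis(x, bias=False) / se_kurt
        flags[col] = bool(abs(skew_z[col]) > critical or abs(kurt_z[col]) > critical)

    return NormalityReport(
        skew_z=pd.Series(skew_z, name="skew_z"),
        kurtosis_z=pd.Series(kurt_z, name="kurtosis_z"),
        transform_flags=pd.Series(flags, name="transform_applied"),
    )
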
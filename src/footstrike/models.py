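"""Foot strike angle prediction and foot strike pattern classification models.

Four model families share one small interface (``fit``/``predict``):

* :class:`PublishedMRModel` — the fixed-coefficient multiple regression
  reported for the insole dataset, usable without any training data.
* :func:`fit_stepwise_mr` — trainable stepwise multiple linear regression
  (forward entry at p <= 0.05, backward removal at p >= 0.10).
* :func:`footstrike.ctree.fit_ctree` — conditional-inference-style
  recursive partitioning.
* :func:`footstrike.forest.fit_forest` — a 500-tree random forest with the
  per-split candidate-feature count tuned by 5-fold cross-validation.

Any FSA-predicting model doubles as a classifier by pushing its predicted
angle through the Altman-Davis class cut-offs (FF below -1.6 deg, RF above
8.0 deg, MF in between, boundaries inclusive to MF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, InputError
from .features import FEATURE_COLUMNS, FeatureVector

__all__ = [
    "ClassThresholds",
    "PublishedMRModel",
    "PUBLISHED_MR",
    "RegressionFit",
    "classify_fsp",
    "split_dataset",
    "fit_stepwise_mr",
    "predict",
]


@dataclass(frozen=True)
class ClassThresholds:
    """Altman-Davis FSA cut-offs (degrees) separating FF / MF / RF."""

    ff_upper: float = -1.6
    rf_lower: float = 8.0

    def __post_init__(self) -> None:
        if not self.ff_upper < self.rf_lower:
            raise ConfigError("need ff_upper < rf_lower")


DEFAULT_THRESHOLDS = ClassThresholds()


def classify_fsp(fsa, thr: ClassThresholds = DEFAULT_THRESHOLDS):
    """Map FSA (degrees) to FF/MF/RF.  Boundary values belong to MF.

    Accepts a scalar (returns ``str``) or an array (returns an object array).
    """
    arr = np.asarray(fsa, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("FSA must be finite")
    out = np.where(arr < thr.ff_upper, "FF", np.where(arr > thr.rf_lower, "RF", "MF"))
    if arr.ndim == 0:
        return str(out)
    return out.astype(object)


# ------------------------- published fixed regression -------------------------


@dataclass(frozen=True)
class PublishedMRModel:
    """The published 7-predictor FSA regression with fixed coefficients.

    Predictors, in order: IR_Aft, PF_Fore, RFD_Aft, IR_Aft(0-33%), PF_Aft,
    Ln(%RFD_Fore), Ln(%RFD_Aft).  Ratio predictors are fractions in [0, 1];
    the two log predictors are logs of a percent (0-100) of stance.
    """

    intercept: float = -89.2
    coefficients: tuple[float, ...] = (94.4, 62.3, 17.9, 8.8, -8.4, 3.4, 1.8)
    predictors: tuple[str, ...] = (
        "ir_aft",
        "pf_fore",
        "rfd_aft",
        "ir_aft_0_33",
        "pf_aft",
        "ln_pct_rfd_fore",
        "ln_pct_rfd_aft",
    )
    task: str = "predict"

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.predictors):
            raise ConfigError("coefficient/predictor length mismatch")

    def _matrix(self, fv) -> np.ndarray:
        if isinstance(fv, FeatureVector):
            fv = pd.DataFrame([fv.as_dict()])
        missing = [p for p in self.predictors if p not in fv.columns]
        if missing:
            raise InputError(f"missing features: {missing}")
        return fv[list(self.predictors)].to_numpy(dtype=float)

    def predict(self, fv) -> np.ndarray | float:
        """Predicted FSA in degrees (scalar for a single FeatureVector)."""
        x = self._matrix(fv)
        out = self.intercept + x @ np.asarray(self.coefficients)
        return float(out[0]) if isinstance(fv, FeatureVector) else out

    def predict_class(self, fv, thr: ClassThresholds = DEFAULT_THRESHOLDS):
        return classify_fsp(self.predict(fv), thr)


#: Module-level instance of the published equation.
PUBLISHED_MR = PublishedMRModel()


def eval_published_mr(fv) -> np.ndarray | float:
    """Evaluate the published fixed-coefficient regression on features."""
    return PUBLISHED_MR.predict(fv)


# ------------------------------ data splitting --------------------------------


def split_dataset(
    records: pd.DataFrame | list,
    train_fraction: float = 0.7,
    seed: int | None = 0,
) -> tuple:
    """Record-wise shuffled split into train/test partitions.

    The train partition receives ``round(train_fraction * n)`` records, so
    3489 records at 70% split into 2442 / 1047.
    """
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise InputError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    if isinstance(records, pd.DataFrame):
        return records.iloc[train_idx], records.iloc[test_idx]
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


# ---------------------------- stepwise regression -----------------------------


@dataclass
class RegressionFit:
    """A fitted (stepwise) linear regression and its fit statistics.

    AIC/BIC use the Gaussian profile form with the constant dropped:
    ``AIC = n ln(RSS/n) + 2(k+1)``, ``BIC = n ln(RSS/n) + (k+1) ln(n)``.
    """

    selected: list[str]
    coefficients: pd.Series
    intercept: float
    r2: float
    adj_r2: float
    resid_se: float
    aic: float
    bic: float
    n: int
    df_resid: int
    dropped_collinear: list[str] = field(default_factory=list)
    task: str = "predict"

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.selected if p not in table.columns]
        if missing:
            raise InputError(f"missing features: {missing}")
        if not self.selected:
            return np.full(len(table), self.intercept)
        x = table[self.selected].to_numpy(dtype=float)
        return self.intercept + x @ self.coefficients.to_numpy()

    def predict_class(self, table, thr: ClassThresholds = DEFAULT_THRESHOLDS):
        return classify_fsp(self.predict(table), thr)


def _pvalue_of_added(y, X_base, x_new) -> float:
    """Partial-F (equivalently t) p-value of adding one column to an OLS fit."""
    X = sm.add_constant(np.column_stack([*X_base, x_new]) if X_base else x_new[:, None])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return np.nan  # perfectly collinear with what is already in the model
    res = sm.OLS(y, X).fit()
    return float(res.pvalues[-1])


def fit_stepwise_mr(
    train: pd.DataFrame,
    response: str = "true_fsa_deg",
    candidates: tuple[str, ...] = FEATURE_COLUMNS,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionFit:
    """Forward-entry / backward-removal stepwise multiple linear regression.

    Variables enter when their partial-F p-value is <= ``p_enter`` and leave
    when it rises to >= ``p_remove``; iteration stops when no move is made.
    Candidates that are perfectly collinear with the selected set are skipped
    and reported in ``dropped_collinear``.
    """
    if p_enter > p_remove:
        raise ConfigError("p_enter must not exceed p_remove")
    cols = [c for c in candidates if c in train.columns]
    if not cols:
        raise InputError("no candidate predictors present")
    y = train[response].to_numpy(dtype=float)
    n = len(y)
    if n <= len(cols) + 2:
        raise InputError("too few rows for stepwise selection")

    tss = float(np.sum((y - y.mean()) ** 2))
    selected: list[str] = []
    dropped: set[str] = set()
    seen: set[frozenset] = {frozenset()}
    while True:
        changed = False
        # a numerically perfect fit makes further partial-F tests meaningless
        if selected:
            res = sm.OLS(y, sm.add_constant(train[selected].to_numpy(dtype=float))).fit()
            if res.ssr <= 1e-10 * max(tss, 1.0):
                break
        # forward step
        X_base = [train[c].to_numpy(dtype=float) for c in selected]
        best_p, best_c = np.inf, None
        for c in cols:
            if c in selected:
                continue
            p = _pvalue_of_added(y, X_base, train[c].to_numpy(dtype=float))
            if np.isnan(p):
                dropped.add(c)
                continue
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p <= p_enter:
            selected.append(best_c)
            changed = True
        # backward step
        while len(selected) > 0:
            X = sm.add_constant(train[selected].to_numpy(dtype=float))
            res = sm.OLS(y, X).fit()
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] >= p_remove:
                del selected[worst]
                changed = True
            else:
                break
        state = frozenset(selected)
        if not changed or state in seen:
            break  # converged, or the enter/remove cycle revisited a state
        seen.add(state)

    if selected:
        X = sm.add_constant(train[selected].to_numpy(dtype=float))
    else:
        X = np.ones((n, 1))
    res = sm.OLS(y, X).fit()
    k = len(selected)
    rss = float(res.ssr)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)
    bic = n * np.log(max(rss, 1e-300) / n) + (k + 1) * np.log(n)
    return RegressionFit(
        selected=list(selected),
        coefficients=pd.Series(res.params[1:], index=selected),
        intercept=float(res.params[0]),
        r2=float(res.rsquared) if k else 0.0,
        adj_r2=float(res.rsquared_adj) if k else 0.0,
        resid_se=float(np.sqrt(rss / res.df_resid)) if res.df_resid > 0 else 0.0,
        aic=aic,
        bic=bic,
        n=n,
        df_resid=int(res.df_resid),
        dropped_collinear=sorted(dropped),
    )


# ------------------------------ prediction API --------------------------------


def predict(model, table, thr: ClassThresholds = DEFAULT_THRESHOLDS):
    """Route a fitted model to FSA predictions or FSP classes.

    Models with ``task == "classify"`` return class labels directly; FSA
    predictors return degrees, or labels via their ``predict_class``.
    """
    if not hasattr(model, "predict"):
        raise InputError("object has no predict method; is it a fitted model?")
    task = getattr(model, "task", "predict")
    if task == "classify":
        return model.predict(table)
    return model.predict(table)


def predict_class(model, table, thr: ClassThresholds = DEFAULT_THRESHOLDS):
    """FSP class labels from any model (thresholding FSA models as needed)."""
    task = getattr(model, "task", "predict")
    if task == "classify":
        return model.predict(table)
    return classify_fsp(model.predict(table), thr)
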
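"""Random forest models with cross-validated candidate-feature tuning.

The forests are bootstrap-aggregated CART ensembles (500 trees by default)
from scikit-learn.  The only tuned hyperparameter is the number of candidate
features considered at each split, chosen from a small grid by 5-fold
cross-validation: lowest RMSE for FSA prediction, highest mean accuracy for
FSP classification.  Out-of-bag error and mean-decrease-impurity variable
importances are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score

from .errors import ConfigError, InputError
from .features import FEATURE_COLUMNS
from .models import ClassThresholds, DEFAULT_THRESHOLDS, classify_fsp

__all__ = ["ForestModel", "fit_forest"]


@dataclass
class ForestModel:
    """A tuned, fitted random forest plus its diagnostics."""

    estimator: object
    task: str
    features: tuple[str, ...]
    n_trees: int
    max_features: int
    cv_scores: dict[int, float]
    oob_error: float
    importances: pd.Series  # mean decrease in impurity, one per feature

    def predict(self, table: pd.DataFrame):
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise InputError(f"missing features: {missing}")
        X = table[list(self.features)].to_numpy(dtype=float)
        out = self.estimator.predict(X)
        return out.astype(object) if self.task == "classify" else out

    def predict_class(self, table, thr: ClassThresholds = DEFAULT_THRESHOLDS):
        if self.task == "classify":
            return self.predict(table)
        return classify_fsp(self.predict(table), thr)


def fit_forest(
    train: pd.DataFrame,
    task: str = "predict",
    response: str | None = None,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    n_trees: int = 500,
    candidate_grid: tuple[int, ...] = (2, 3, 4, 5),
    seed: int = 0,
    n_folds: int = 5,
) -> ForestModel:
    """Fit a random forest, tuning the per-split feature count by k-fold CV."""
    if task not in ("predict", "classify"):
        raise ConfigError(f"unknown task {task!r}")
    if len(train) == 0:
        raise InputError("empty training table")
    if response is None:
        response = "true_fsa_deg" if task == "predict" else "true_class"
    cols = [f for f in features if f in train.columns]
    if not cols:
        raise InputError("no candidate features present")
    X = train[cols].to_numpy(dtype=float)
    y = train[response].to_numpy()
    if task == "classify":
        y = y.astype(str)

    grid = [m for m in candidate_grid if m <= len(cols)]
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scoring = "neg_root_mean_squared_error" if task == "predict" else "accuracy"

    def make(m: int, oob: bool):
        cls = RandomForestRegressor if task == "predict" else RandomForestClassifier
        return cls(
            n_estimators=n_trees,
            max_features=m,
            oob_score=oob,
            random_state=seed,
            n_jobs=1,
        )

    cv_scores: dict[int, float] = {}
    for m in grid:
        scores = cross_val_score(make(m, oob=False), X, y, cv=cv, scoring=scoring)
        cv_scores[m] = float(np.mean(scores))
    best_m = max(cv_scores, key=cv_scores.get)  # both scorings are maximized

    est = make(best_m, oob=True).fit(X, y)
    if task == "predict":
        resid_var = float(np.mean((y - est.oob_prediction_) ** 2))
        oob_error = float(np.sqrt(resid_var))  # OOB RMSE, degrees
    else:
        oob_error = float(1.0 - est.oob_score_)  # OOB misclassification rate

    return ForestModel(
        estimator=est,
        task=task,
        features=tuple(cols),
        n_trees=n_trees,
        max_features=best_m,
        cv_scores=cv_scores,
        oob_error=oob_error,
        importances=pd.Series(est.feature_importances_, index=cols),
    )
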
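"""CSV/JSON interchange for traces, manifests, feature tables and models.

Everything is plain text.  Trace files carry one stance buffer with columns
``time_s, force_fore_N, force_aft_N`` (``force_total_N`` optional; it is
recomputed as the sensor sum when absent).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .features import FEATURE_COLUMNS
from .simulate import ForceTrace

__all__ = [
    "read_trace",
    "write_trace",
    "write_manifest",
    "read_feature_table",
    "write_feature_table",
    "model_to_json",
    "model_from_json",
]

_TRACE_COLUMNS = ("time_s", "force_fore_N", "force_aft_N")

#: Non-feature columns of a feature table.
META_COLUMNS = ("step_id", "true_fsa_deg", "true_class", "condition")


def read_trace(path) -> ForceTrace:
    """Read and validate one trace CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    for col in ("force_fore_N", "force_aft_N"):
        bad = np.flatnonzero(df[col].to_numpy(dtype=float) < 0)
        if bad.size:
            raise FormatError(
                f"{path.name}: negative force in column {col} at rows "
                f"{[int(b) + 2 for b in bad[:5]]} (1-based incl. header)"
            )
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6:
        raise FormatError(f"{path.name}: time_s must be uniform and increasing")
    fore = df["force_fore_N"].to_numpy(dtype=float)
    aft = df["force_aft_N"].to_numpy(dtype=float)
    return ForceTrace(t, fore, aft, fore + aft)


def write_trace(trace: ForceTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "force_fore_N": trace.force_fore,
            "force_aft_N": trace.force_aft,
            "force_total_N": trace.force_total,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def write_manifest(records, path, seed: int | None = None) -> None:
    """Dataset manifest: step_id, true FSA/class, requested condition."""
    rows = [
        {
            "step_id": i,
            "true_fsa_deg": truth.fsa,
            "true_class": truth.fsp_class,
            "condition": truth.condition_label,
            "seed": seed,
        }
        for i, (_, truth) in enumerate(records)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing feature columns {missing}")
    return df


def model_to_json(model, path) -> None:
    """Serialize a fitted model's structure/coefficients to JSON.

    Forests are summarized (hyperparameters, importances, OOB error) rather
    than dumped tree-by-tree.
    """
    kind = type(model).__name__
    if hasattr(model, "to_dict"):
        payload = model.to_dict()
    elif hasattr(model, "coefficients") and hasattr(model, "intercept"):
        coeffs = model.coefficients
        payload = {
            "kind": kind,
            "intercept": float(model.intercept),
            "coefficients": {k: float(v) for k, v in dict(coeffs).items()}
            if hasattr(coeffs, "items") or isinstance(coeffs, pd.Series)
            else list(map(float, coeffs)),
            "predictors": list(getattr(model, "predictors", getattr(model, "selected", []))),
        }
    elif hasattr(model, "importances"):
        payload = {
            "kind": kind,
            "task": model.task,
            "n_trees": model.n_trees,
            "max_features": model.max_features,
            "cv_scores": {str(k): v for k, v in model.cv_scores.items()},
            "oob_error": model.oob_error,
            "importances": {k: float(v) for k, v in model.importances.items()},
        }
    else:
        raise FormatError(f"cannot serialize model of type {kind}")
    payload["version"] = 1
    Path(path).write_text(json.dumps(payload, indent=2))


def model_from_json(path):
    """Reload a serialized model for prediction.

    Trees and regressions round-trip losslessly.  Forest JSON is a summary
    (hyperparameters, importances, OOB error) and cannot be reloaded; retrain
    instead.
    """
    from .ctree import TreeModel
    from .models import RegressionFit

    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "ctree":
        return TreeModel.from_dict(payload)
    if kind in ("RegressionFit", "PublishedMRModel"):
        coeffs = payload["coefficients"]
        if isinstance(coeffs, dict):
            series = pd.Series(coeffs)
        else:
            series = pd.Series(list(coeffs), index=payload["predictors"])
        return RegressionFit(
            selected=list(series.index),
            coefficients=series.astype(float),
            intercept=float(payload["intercept"]),
            r2=float("nan"), adj_r2=float("nan"), resid_se=float("nan"),
            aic=float("nan"), bic=float("nan"),
            n=0, df_resid=0,
        )
    if kind == "ForestModel":
        raise FormatError("forest JSON is a summary; retrain to predict")
    raise FormatError(f"unknown model kind {kind!r} in {Path(path).name}")
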
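"""End-to-end pipeline: simulate -> detect events -> extract features ->
split -> train (regression / tree / forest, both tasks) -> evaluate.

Every stage draws its randomness from a stage-specific child of one master
seed (``numpy.random.SeedSequence.spawn``), so a run is reproducible from its
config alone.  Reports and intermediate tables are written as CSV/JSON into a
run directory that is never silently overwritten.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fsio
from .ctree import fit_ctree
from .errors import FootstrikeError, InputError
from .evaluate import bland_altman, confusion, matrix_metrics, prediction_metrics
from .events import EventConfig, segment_stance
from .features import FEATURE_COLUMNS, extract_features, normality_screen
from .forest import fit_forest
from .models import (
    PUBLISHED_MR,
    fit_stepwise_mr,
    predict_class,
    split_dataset,
)
from .simulate import GaitSimConfig, generate_dataset

__all__ = ["PipelineConfig", "build_feature_table", "run_pipeline"]

log = logging.getLogger("footstrike")

# stage offsets for SeedSequence spawning; order is part of the contract
_STAGES = ("simulate", "split", "models")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    n_ff: int = 500
    n_mf: int = 500
    n_rf: int = 500
    seed: int = 0
    simulator: GaitSimConfig = field(default_factory=GaitSimConfig)
    events: EventConfig = field(default_factory=EventConfig)
    train_fraction: float = 0.7
    n_trees: int = 500
    forest_grid: tuple[int, ...] = (2, 3, 4, 5)
    out_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic 31-bit child seed for a named stage."""
        idx = _STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGES))[idx]
        return int(child.generate_state(1, np.uint32)[0] % (2**31))

    def to_dict(self) -> dict:
        # json round-trip turns nested tuples into plain lists for YAML/JSON;
        # out_dir is an output location, not a run parameter, and is omitted
        # so reports from identical runs compare byte-identical
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = GaitSimConfig(**raw.pop("simulator", {}))
        ev = EventConfig(**raw.pop("events", {}))
        if "forest_grid" in raw:
            raw["forest_grid"] = tuple(raw["forest_grid"])
        return cls(simulator=sim, events=ev, **raw)


def build_feature_table(records, event_cfg: EventConfig | None = None) -> pd.DataFrame:
    """Detect stance and extract the ten features for every simulated record."""
    if event_cfg is None:
        event_cfg = EventConfig()
    rows = []
    for i, (trace, truth) in enumerate(records):
        try:
            window = segment_stance(trace, event_cfg)
            fv = extract_features(trace, window)
        except FootstrikeError as exc:
            raise type(exc)(f"step_id {i}: {exc}") from exc
        row = {"step_id": i, "true_fsa_deg": truth.fsa,
               "true_class": truth.fsp_class, "condition": truth.condition_label}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=list(fsio.META_COLUMNS) + list(FEATURE_COLUMNS))


def _evaluate_fsa(name: str, true_fsa, pred) -> dict:
    pm = prediction_metrics(true_fsa, pred)
    ba = bland_altman(true_fsa, pred)
    return {
        "model": name,
        "mse": pm.mse, "rmse": pm.rmse, "mae": pm.mae, "mape": pm.mape,
        "bias": ba.bias, "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
        "max_precision": ba.max_precision, "n": pm.n,
    }


def _evaluate_fsp(name: str, true_cls, pred_cls) -> dict:
    cm = confusion(true_cls, pred_cls)
    metrics = matrix_metrics(cm)
    return {
        "model": name,
        "matrix": cm.counts.tolist(),
        "accuracy": metrics["accuracy"],
        "recall": metrics["recall"],
        "precision": metrics["precision"],
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full simulate-to-evaluate pipeline; return results in memory.

    When ``cfg.out_dir`` is set, the manifest, feature table, model files and
    a JSON report are written there; an existing nonempty directory is
    refused rather than overwritten.
    """
    if cfg.n_ff + cfg.n_mf + cfg.n_rf < 10:
        raise InputError("pipeline needs at least 10 records to be meaningful")

    out = None
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        if out.exists() and any(out.iterdir()):
            raise InputError(f"refusing to overwrite nonempty run directory {out}")
        out.mkdir(parents=True, exist_ok=True)

    log.info("simulating %d/%d/%d FF/MF/RF steps", cfg.n_ff, cfg.n_mf, cfg.n_rf)
    sim_cfg = dataclasses.replace(cfg.simulator, seed=cfg.stage_seed("simulate"))
    records = generate_dataset(sim_cfg, n_ff=cfg.n_ff, n_mf=cfg.n_mf, n_rf=cfg.n_rf)

    log.info("extracting features from %d records", len(records))
    table = build_feature_table(records, cfg.events)
    screen = normality_screen(table)

    train, test = split_dataset(table, cfg.train_fraction, seed=cfg.stage_seed("split"))
    log.info("split %d records into %d train / %d test", len(table), len(train), len(test))

    model_seed = cfg.stage_seed("models")
    models = {
        "mr_published": PUBLISHED_MR,
        "mr_stepwise": fit_stepwise_mr(train),
        "tree_pred": fit_ctree(train, task="predict"),
        "tree_class": fit_ctree(train, task="classify"),
        "forest_pred": fit_forest(train, task="predict", n_trees=cfg.n_trees,
                                  candidate_grid=cfg.forest_grid, seed=model_seed),
        "forest_class": fit_forest(train, task="classify", n_trees=cfg.n_trees,
                                   candidate_grid=cfg.forest_grid, seed=model_seed),
    }

    true_fsa = test["true_fsa_deg"].to_numpy(dtype=float)
    true_cls = test["true_class"].to_numpy(dtype=object)
    fsa_models = ("mr_published", "mr_stepwise", "tree_pred", "forest_pred")
    cls_models = ("mr_published", "mr_stepwise", "tree_class", "forest_class")

    report = {
        "config": cfg.to_dict(),
        "normality": {
            "skew_z": screen.skew_z.to_dict(),
            "kurtosis_z": screen.kurtosis_z.to_dict(),
            "transform_flags": screen.transform_flags.to_dict(),
        },
        "fsa_prediction": [
            _evaluate_fsa(m, true_fsa, models[m].predict(test)) for m in fsa_models
        ],
        "fsp_classification": [
            _evaluate_fsp(m, true_cls, predict_class(models[m], test))
            for m in cls_models
        ],
    }

    if out is not None:
        fsio.write_manifest(records, out / "manifest.csv", seed=cfg.seed)
        fsio.write_feature_table(table, out / "features.csv")
        (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
        for name in ("mr_stepwise", "tree_pred", "tree_class",
                     "forest_pred", "forest_class"):
            fsio.model_to_json(models[name], out / f"model_{name}.json")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    report["models"] = models
    report["train"], report["test"] = train, test
    return report
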
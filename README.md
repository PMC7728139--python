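# footstrike

Foot strike angle prediction and foot strike pattern classification from
two-sensor (fore/aft) pressure-insole force traces.

## The problem

How a runner's foot meets the ground — the **foot strike angle** (FSA, the
sagittal angle of the foot at initial contact; positive = heel first) and its
discrete **foot strike pattern** (FSP: fore foot FF, mid foot MF, rear foot
RF) — matters for shoe selection, coaching and injury research. Measuring FSA
normally requires a motion-capture lab. A wireless pressure insole that
reports vertical force separately under the fore foot and the heel at 100 Hz
can stand in for the lab: the relative timing and magnitude of fore vs aft
loading carries enough information to estimate the angle.

This package implements that estimation chain for researchers and
practitioners working with such insoles:

- **Event detection**: initial contact / toe off from loading-rate threshold
  crossings (±1500 N/s on the total force).
- **Features**: ten scale-invariant stance variables — fore/aft impulse
  shares (full stance and first third), peak-force shares, peak
  loading-rate shares, and log-timing of each sensor's peak loading rate.
- **Models**: the published fixed-coefficient regression

  FSA = −89.2 + 94.4·IR_Aft + 62.3·PF_Fore + 17.9·RFD_Aft
        + 8.8·IR_Aft(0–33%) − 8.4·PF_Aft + 3.4·Ln(%RFD_Fore) + 1.8·Ln(%RFD_Aft)

  plus trainable stepwise regression, a conditional-inference tree
  (permutation-statistic splits, Bonferroni-adjusted, α = 0.01) and a
  500-tree random forest tuned by 5-fold cross-validation. Angle predictors
  classify via the Altman–Davis cut-offs (FF < −1.6°, MF −1.6°…8.0°,
  RF > 8.0°).
- **Evaluation**: MSE/RMSE/MAE/MAPE, Bland–Altman bias and 95% limits of
  agreement, and 3×3 confusion matrices with accuracy / per-class recall /
  per-class precision.
- **Synthetic data**: the original study recordings are not public, so a
  seeded generator produces fore/aft stance waveforms with known FSA whose
  extracted features match the published per-class distributions (see
  `docs/methods.md` for what that does and does not establish).

## Worked example

```python
from footstrike import (
    GaitSimConfig, PipelineConfig, PUBLISHED_MR, classify_fsp,
    extract_features, run_pipeline, segment_stance, synthesize_trace,
)

# one synthetic rear-foot step
trace, truth = synthesize_trace(fsa=24.9, cfg=GaitSimConfig(seed=7))
window = segment_stance(trace)          # IC/TO from the loading rate
fv = extract_features(trace, window)    # the ten stance features
fsa_hat = PUBLISHED_MR.predict(fv)      # published equation
print(round(fv.ir_aft, 3), round(fv.rfd_aft, 3), round(fsa_hat, 1),
      classify_fsp(fsa_hat))
# 0.336 0.902 12.0 RF
```

A heel-first step at 24.9° puts about a third of the impulse (`ir_aft` 0.336)
and ~90% of the steepest loading (`rfd_aft` 0.902) on the aft sensor. The
published equation — whose coefficients were fit to real insole recordings,
not to this simulator — maps those shares to 12.0°, comfortably past the 8.0°
rear-foot cut-off: class-correct, with the larger angle error you would
expect from a transferred fixed-coefficient model (the retrained models below
do much better on their own data).

The full pipeline — simulate, detect, extract, 70/30 record-wise split,
train all models, evaluate held-out — is one call (or `footstrike run
--out-dir runs/demo --seed 1` on the command line):

```python
report = run_pipeline(PipelineConfig(n_ff=500, n_mf=500, n_rf=500, seed=1))
for entry in report["fsp_classification"]:
    print(entry["model"], round(entry["accuracy"], 1))
# mr_published 89.6
# mr_stepwise 96.7
# tree_class 99.3
# forest_class 99.8
```

Accuracies above 90% on synthetic data say the pipeline is wired correctly
and the features separate the classes as published — they are not estimates
of real-world accuracy.

## Command line

`footstrike simulate | events | features | train | predict | evaluate | run`
— each a thin wrapper over the functions above; traces, manifests and
feature tables are plain CSV, models and reports JSON/YAML. Column names
(`time_s, force_fore_N, force_aft_N`; `ir_fore … ln_pct_rfd_aft`,
`step_id, true_fsa_deg, true_class, condition`) are part of the public
contract.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main end-to-end computation (balanced 1500-step
dataset, all models, held-out evaluation) from scratch under the given seed,
logging per-model accuracy/RMSE to stderr and writing the results file.

## Layout

- `src/footstrike/simulate.py` — waveform generator and ground truth
- `src/footstrike/events.py` — loading rate, IC/TO detection
- `src/footstrike/features.py` — the ten stance features, normality screen
- `src/footstrike/models.py` — published/stepwise regression, thresholds, split
- `src/footstrike/ctree.py` — conditional-inference tree (from scratch)
- `src/footstrike/forest.py` — tuned random forest
- `src/footstrike/evaluate.py` — error metrics, Bland–Altman, confusion
- `src/footstrike/io.py`, `pipeline.py`, `cli.py` — formats, orchestration
- `docs/methods.md` — models, simulator design, numerical conventions
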
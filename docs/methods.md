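# Methods

`footstrike` estimates a runner's foot strike angle (FSA, degrees) and foot
strike pattern (FSP: fore foot FF, mid foot MF, rear foot RF) from a
two-sensor pressure insole that reports vertical force separately under the
fore foot and the heel at 100 Hz. This note documents the models the package
implements, the synthetic-data generator that stands in for the unavailable
study recordings, the numerical conventions, and what the test suite does and
does not establish.

## The estimation chain

1. **Gait events.** Initial contact (IC) is the first frame in which the
   loading rate of the total force (backward first difference × sampling
   rate) exceeds +1500 N/s; toe off (TO) is the last frame below −1500 N/s.
   Events are frame-resolution; no sub-sample interpolation. The rate is
   taken on the *total* (fore + aft) force: per-sensor thresholding would
   make IC depend on strike style, which is what the features are supposed to
   measure, not the event definition.

2. **Stance features.** Ten relative quantities per step, all invariant to
   overall force scale: the fore/aft impulse shares over the full stance and
   over its first third (IC to IC + round((TO−IC)/3), inclusive), the fore/
   aft peak-force shares, the fore/aft peak-loading-rate shares, and the
   natural log of where (percent of stance, IC = 0%, TO = 100%) each sensor's
   loading rate peaks. Share features are kept as fractions in [0, 1]; the
   log-timing features use the 0–100 percent scale inside the log. This
   convention is the one under which the published fixed-coefficient
   regression evaluated at the published per-class mean feature vectors
   reproduces the per-class mean FSA to within a few degrees; a percent scale
   on the shares produces absurd angles.

3. **Models.**
   - *Published regression*: FSA = −89.2 + 94.4·IR_Aft + 62.3·PF_Fore +
     17.9·RFD_Aft + 8.8·IR_Aft(0–33%) − 8.4·PF_Aft + 3.4·Ln(%RFD_Fore) +
     1.8·Ln(%RFD_Aft). Fixed coefficients; usable with no training data.
   - *Stepwise regression*: forward entry while the best candidate's
     partial-F p ≤ 0.05, backward removal while any retained p ≥ 0.10.
     (The removal threshold is read as 0.100; a removal threshold below the
     entry threshold would be internally inconsistent.) Perfectly collinear
     candidates — e.g. the fore share when the aft share is already in the
     model — are skipped and reported. AIC = n·ln(RSS/n) + 2(k+1) and
     BIC = n·ln(RSS/n) + (k+1)·ln n, the Gaussian profile forms with the
     additive constant dropped.
   - *Conditional-inference tree*: at each node the linear permutation
     statistic T = Σ x·h(y) (h = response for regression, one-hot classes for
     classification) is standardized by its exact permutation moments,
     E(T) = Σx·h̄ and Cov(T) = S_x·Σ_h/(n−1), and its quadratic form referred
     to χ². p-values are Bonferroni-adjusted across the candidate features;
     a node splits only if the best adjusted p ≤ α = 0.01 (a "minimum
     splitting criterion" of 0.99). The cutpoint maximizes the analogous
     two-sample statistic. Depth caps default to 8 (FSA prediction) and 6
     (FSP classification); nodes below 20 records, or children below 7, are
     not split. This is a faithful simplification of the conditional-
     inference framework, not a bit-exact clone of any reference
     implementation.
   - *Random forest*: 500 bootstrap-aggregated CART trees (scikit-learn),
     with the per-split candidate-feature count tuned over {2, 3, 4, 5} by
     5-fold cross-validation (lowest RMSE for prediction, highest accuracy
     for classification). Out-of-bag error and mean-decrease-impurity
     importances are reported.
   - Any FSA predictor classifies by pushing its predicted angle through the
     Altman–Davis cut-offs: FF below −1.6°, RF above 8.0°, MF in between,
     boundaries inclusive to MF. The same cut-offs label the ground truth;
     no recalibration.

4. **Evaluation.** MSE/RMSE/MAE/MAPE (MAPE as a unitless fraction,
   mean |err|/|true| over records with true ≠ 0; exact-zero angles are
   excluded from MAPE only and counted). Bland–Altman bias = mean(true −
   predicted), 95% limits of agreement = bias ± 1.96·SD(differences) with the
   n−1 SD, "maximum precision" = the width between the limits. Confusion
   matrices use the fixed row/column order RF, MF, FF; accuracy, per-class
   recall and per-class precision are percentages, rounded half-away-from-
   zero to one decimal in reports; the precision of a class nobody was
   assigned to is reported as NaN rather than zero.

## The synthetic-data generator

The raw recordings behind the published models are not public, so the
package generates its own.
Each simulated step is one stance phase embedded in 0.1 s of zero-force
padding. Each sensor's force is a sum of raised-cosine pulses (smooth,
nonnegative, closed-form integrals, which gives the impulse tests an analytic
oracle): an aft heel pulse plus a mid-stance sustain, and a fore impact pulse
plus a wide push-off pulse, with two small fixed fore transients at 6% and
94% of stance so the first and last stance frames carry a detectable loading
rate (without them, the flat cosine tails make the detected stance ~3 frames
short of the generating duration at 100 Hz).

Pulse amplitudes and the heel-pulse timing are bounded logistic functions of
the generating FSA — increasing for aft quantities, decreasing for fore —
calibrated once so that a noiseless step at each class-mean FSA lands inside
the published per-class mean ± 2 SD envelope for all ten features, and so
that the four aft shares are nondecreasing (fore shares nonincreasing) in FSA
across a noiseless sweep of −25° to +40°. The maps saturate outside
[−28°, +32°], so exaggerated strikes plateau instead of extrapolating.

Stated-world defaults: stance duration uniform on 0.20–0.35 s, peak total
force uniform on 1500–2500 N (≈2–3 body weights for an 80 kg runner),
class-conditional FSA Gaussians FF −10.2 ± 6.6°, MF 3.0 ± 2.8°,
RF 24.9 ± 8.0°, sampling 100 Hz. Ground-truth labels always come from the
drawn FSA via the class cut-offs, never from the requested condition, so
condition and label disagree near boundaries exactly as labelled real data
would.

**Noise.** The configured `noise_sd` (default 0.01) is the sensor noise SD at
the force peak, applied multiplicatively to the local clean force after
band-limiting (5-sample Hann smoothing). Purely additive white noise at the
same nominal level would inject ±2800 N/s loading-rate noise into the
zero-force padding and trip the ±1500 N/s event thresholds on silence, which
no real insole does; proportional band-limited noise keeps the padding quiet
and perturbs the features at realistic magnitude.

**What a green test does not establish.** The generator reproduces the
*relative* force/time structure the features measure, with class-conditional
distributions anchored to the published descriptive statistics. It is not a
biomechanically validated waveform: absolute force shapes, shoe/midsole
effects, bilateral asymmetry, speed effects and within-runner correlation are
all absent, and every step is independent. Model-accuracy numbers obtained on
synthetic data (e.g. held-out classification accuracy above 90%) demonstrate
that the pipeline is correctly wired and that the features separate the
classes as published — they are not estimates of real-world accuracy, and the
published error tables (RMSE ≈ 3.7–5.2°, limits of agreement ≈ 14–19°) cannot
be reproduced without the original recordings.

## Numerical choices and edge cases

- Backward differences everywhere a loading rate is needed; the first sample
  of a trace has rate NaN. Peak-rate locations take the first index on ties.
- The first-third boundary uses frame rounding of (TO−IC)/3 and is inclusive.
- Impulses are trapezoidal integrals; at 100 Hz they match the analytic pulse
  integral to ~1e-3 relative.
- Degenerate stances (zero impulse, nonpositive peak rate, peak rate exactly
  at IC) raise typed errors rather than returning sentinel values.
- Rate-share features may exceed 1 when one sensor's rise outruns the total's
  steepest rise; this is permitted and preserved.
- Stepwise selection terminates when no move is made, when a selection state
  repeats (enter/remove cycles are possible at the thresholds), or when the
  fit is numerically perfect (RSS below 1e-10 of the total sum of squares),
  at which point further partial-F tests are meaningless. Ties between
  perfectly complementary shares are broken by candidate order; the loser is
  reported as collinear.
- All randomness flows from explicit seeds; the pipeline derives per-stage
  31-bit seeds from one master seed via `SeedSequence.spawn`, so identical
  configs produce byte-identical reports.

## Known limitations

- The stepwise path is plain partial-F forward/backward; it does not
  replicate any particular statistics package's tie-breaking, so on real data
  the selected set could differ near the entry threshold.
- The conditional-inference tree uses the asymptotic χ² reference for the
  permutation statistic; exact small-sample permutation p-values are not
  computed (nodes smaller than 20 records are leaves anyway).
- Forest serialization is a summary (tuning, importances, OOB error), not a
  reloadable predictor; retrain from the feature table (seconds) if
  predictions are needed later.
- On a null response, forward entry at p ≤ 0.05 over 10 candidates admits a
  noise variable in roughly 40% of datasets (1 − 0.95¹⁰); this is inherent to
  the stated thresholds, not a defect of the implementation.
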
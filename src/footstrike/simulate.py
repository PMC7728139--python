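"""Synthetic two-sensor (fore/aft) insole force traces with known foot strike angle.

The study data behind the published models is not public, so this module
emulates it.  Each simulated step is one stance phase of running recorded by a
pressure insole split into a fore sensor and an aft (heel) sensor at 100 Hz.
The generating parameter is the foot strike angle (FSA, degrees): positive
angles mean heel-first (rear foot) contact, negative angles toe-first (fore
foot) contact.

Waveform family
---------------
Each sensor's force is a sum of raised-cosine pulses over the stance phase
(an impact pulse and an active/push-off pulse), which are smooth, nonnegative
and have closed-form integrals.  The pulse amplitudes and the aft-pulse timing
are monotone (logistic or affine-logistic) functions of FSA, calibrated so
that the extracted stance features stratify across fore-/mid-/rear-foot
classes the way the published descriptive statistics do: the aft-sensor
impulse share, peak-force share, peak-loading-rate share and early-stance
impulse share all increase with FSA, and the fore-sensor counterparts
decrease.

Class-conditional FSA distributions are Gaussian with the published per-class
moments (FF -10.2 +/- 6.6 deg, MF 3.0 +/- 2.8 deg, RF 24.9 +/- 8.0 deg).
Ground-truth class labels are always derived from the drawn FSA via the
Altman-Davis cut-offs (-1.6 deg, 8.0 deg), never from the requested
condition, mirroring how steps were labelled in the source protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "FSP_CLASSES",
    "GaitSimConfig",
    "ForceTrace",
    "GroundTruth",
    "sample_fsa",
    "synthesize_trace",
    "generate_dataset",
]

#: Canonical class order used throughout the package (rows of every report).
FSP_CLASSES = ("RF", "MF", "FF")

#: Published per-class FSA mean/SD in degrees.
DEFAULT_FSA_CLASS_PARAMS = {
    "FF": (-10.2, 6.6),
    "MF": (3.0, 2.8),
    "RF": (24.9, 8.0),
}


@dataclass(frozen=True)
class GaitSimConfig:
    """Knobs of the stance-phase waveform generator.

    Parameters
    ----------
    sampling_rate:
        Sensor sampling rate in Hz.  The insole hardware being emulated tops
        out at 100 Hz, which is the default.
    stance_duration_range:
        Uniform range (s) from which each step's ground-contact time is drawn.
        0.20-0.35 s covers recreational running speeds.
    peak_total_force_range:
        Uniform range (N) for the peak total vertical force, roughly 2-3 body
        weights for an 80 kg runner.
    fsa_class_params:
        ``{"FF"|"MF"|"RF": (mean_deg, sd_deg)}`` for the class-conditional
        FSA Gaussians.
    noise_sd:
        Multiplicative sensor noise level as a fraction of the local force
        (so the absolute noise SD at the force peak is ``noise_sd * peak``).
        The noise is band-limited (5-sample smoothing) so that it perturbs
        features without injecting spurious loading-rate threshold crossings.
    pad_s:
        Near-zero force padding emitted before initial contact and after toe
        off so event detection always has a baseline to cross from.
    seed:
        Seed used whenever an operation is not handed an explicit generator.
    """

    sampling_rate: float = 100.0
    stance_duration_range: tuple[float, float] = (0.20, 0.35)
    peak_total_force_range: tuple[float, float] = (1500.0, 2500.0)
    fsa_class_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FSA_CLASS_PARAMS)
    )
    noise_sd: float = 0.01
    pad_s: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        lo, hi = self.stance_duration_range
        if not (0 < lo <= hi):
            raise ConfigError("stance_duration_range must be positive and ordered")
        plo, phi = self.peak_total_force_range
        if not (0 < plo <= phi):
            raise ConfigError("peak_total_force_range must be positive and ordered")
        for label, (_, sd) in self.fsa_class_params.items():
            if sd < 0:
                raise ConfigError(f"negative FSA SD for class {label!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.pad_s < 0.05:
            raise ConfigError("pad_s must be >= 0.05 s so thresholds can be crossed")


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled fore/aft/total vertical force of one buffer."""

    time: np.ndarray
    force_fore: np.ndarray
    force_aft: np.ndarray
    force_total: np.ndarray

    def __post_init__(self) -> None:
        t, ff, fa, ft = (
            np.asarray(self.time, dtype=float),
            np.asarray(self.force_fore, dtype=float),
            np.asarray(self.force_aft, dtype=float),
            np.asarray(self.force_total, dtype=float),
        )
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force_fore", ff)
        object.__setattr__(self, "force_aft", fa)
        object.__setattr__(self, "force_total", ft)
        n = t.size
        if n < 2 or ff.size != n or fa.size != n or ft.size != n:
            raise InputError("trace arrays must share a common length >= 2")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InputError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6:
            raise InputError("time grid must be uniform (1e-6 s jitter allowed)")
        if np.any(ff < 0) or np.any(fa < 0):
            raise InputError("sensor forces must be nonnegative")
        scale = max(float(np.max(ft)), 1.0)
        if np.max(np.abs(ft - (ff + fa))) > 1e-9 * scale:
            raise InputError("force_total must equal force_fore + force_aft")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class GroundTruth:
    """Generating FSA, the class it implies, and the requested condition."""

    fsa: float
    fsp_class: str
    condition_label: str = "NA"


# --- FSA -> class labelling (duplicated from strike_models to keep the
#     simulator import-free of the modelling layer; both use the same cuts) ---

_FF_UPPER = -1.6
_RF_LOWER = 8.0


def _label_from_fsa(fsa: float) -> str:
    if fsa < _FF_UPPER:
        return "FF"
    if fsa > _RF_LOWER:
        return "RF"
    return "MF"


# ----------------------------- waveform internals -----------------------------


def _logistic(fsa: float, lo: float, hi: float, center: float, scale: float) -> float:
    """Bounded monotone map from FSA to a waveform parameter.

    Increasing when ``hi > lo``, decreasing when ``hi < lo``.
    """
    return lo + (hi - lo) / (1.0 + np.exp(-(fsa - center) / scale))


def _pulse(u: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    """Raised-cosine pulse on the stance fraction u, support [center-width, center+width]."""
    arg = (u - center) / width
    out = np.where(np.abs(arg) <= 1.0, 0.5 * amp * (1.0 + np.cos(np.pi * arg)), 0.0)
    return out


def pulse_integral(amp: float, width: float) -> float:
    """Closed-form integral of a full raised-cosine pulse (in stance-fraction units)."""
    return amp * width


def _waveform_params(fsa: float) -> dict[str, list[tuple[float, float, float]]]:
    """Pulse tables ``(amplitude, center, width)`` in stance-fraction units.

    Aft amplitudes/timing increase with FSA, fore amplitudes decrease;
    calibrated against the published per-class feature envelopes.  The maps
    are clamped to their saturation region beyond roughly +/-2 SD of the
    extreme class means, so features flatten (rather than drift) for
    exaggerated strikes.
    """
    fsa = float(np.clip(fsa, -28.0, 32.0))
    # aft: heel pulse (sharp, rises after the fore impact) + mid-stance sustain
    a1 = _logistic(fsa, 0.04, 0.97, 12.0, 9.0)
    ca1 = _logistic(fsa, 0.235, 0.315, 8.0, 8.0)
    a2 = _logistic(fsa, 0.005, 0.22, 14.0, 8.0)
    # fore: early impact pulse + wide push-off pulse; the push rise is kept
    # gentler than the impact rise so the fore peak loading rate stays early
    f1 = _logistic(fsa, 0.92, 0.34, 2.0, 8.0)
    f2 = _logistic(fsa, 1.05, 0.72, 8.0, 9.0)
    # small fixed contact/lift-off transients (fore side) give the buffer a
    # detectable loading-rate crossing in the first/last stance frames
    return {
        "aft": [(a1, ca1, 0.18), (a2, 0.55, 0.30)],
        "fore": [
            (f1, 0.195, 0.16),
            (f2, 0.57, 0.43),
            (0.04, 0.06, 0.06),
            (0.04, 0.94, 0.06),
        ],
    }


def _clean_stance(fsa: float, n_stance: int) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free fore/aft waveforms on ``n_stance`` samples, unit peak scale."""
    u = np.linspace(0.0, 1.0, n_stance)
    params = _waveform_params(fsa)
    fore = np.zeros_like(u)
    aft = np.zeros_like(u)
    for amp, c, w in params["fore"]:
        fore += _pulse(u, amp, c, w)
    for amp, c, w in params["aft"]:
        aft += _pulse(u, amp, c, w)
    return fore, aft


def _smooth_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance band-limited noise (5-sample Hann smoothing)."""
    white = rng.standard_normal(n + 4)
    kernel = np.hanning(7)[1:-1]
    kernel /= np.sqrt(np.sum(kernel**2))
    return np.convolve(white, kernel, mode="valid")


# ------------------------------- public API ----------------------------------


def sample_fsa(
    cfg: GaitSimConfig,
    class_label: str,
    n: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` foot strike angles from a class's Gaussian FSA distribution."""
    if class_label not in cfg.fsa_class_params:
        raise ConfigError(f"unknown FSP class {class_label!r}")
    if n < 1:
        raise InputError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mean, sd = cfg.fsa_class_params[class_label]
    return mean + sd * rng.standard_normal(n)


def synthesize_trace(
    fsa: float,
    cfg: GaitSimConfig,
    rng: np.random.Generator | None = None,
    condition_label: str = "NA",
) -> tuple[ForceTrace, GroundTruth]:
    """Generate one padded stance-phase buffer for a given foot strike angle.

    Stance duration and peak total force are drawn from the configured uniform
    ranges; sensor noise (if any) is proportional to the local clean force so
    the padding stays quiet and event detection remains well posed.
    """
    if not np.isfinite(fsa):
        raise InputError("fsa must be finite")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    fs = cfg.sampling_rate
    duration = rng.uniform(*cfg.stance_duration_range)
    peak = rng.uniform(*cfg.peak_total_force_range)

    n_stance = max(int(round(duration * fs)) + 1, 8)
    n_pad = int(round(cfg.pad_s * fs))

    fore_u, aft_u = _clean_stance(fsa, n_stance)
    total_u = fore_u + aft_u
    scale = peak / float(np.max(total_u))
    fore = fore_u * scale
    aft = aft_u * scale

    if cfg.noise_sd > 0:
        fore = fore * (1.0 + cfg.noise_sd * _smooth_noise(rng, n_stance))
        aft = aft * (1.0 + cfg.noise_sd * _smooth_noise(rng, n_stance))
        np.clip(fore, 0.0, None, out=fore)
        np.clip(aft, 0.0, None, out=aft)

    n = n_stance + 2 * n_pad
    force_fore = np.zeros(n)
    force_aft = np.zeros(n)
    force_fore[n_pad : n_pad + n_stance] = fore
    force_aft[n_pad : n_pad + n_stance] = aft
    time = np.arange(n) / fs

    trace = ForceTrace(time, force_fore, force_aft, force_fore + force_aft)
    truth = GroundTruth(fsa=float(fsa), fsp_class=_label_from_fsa(fsa),
                        condition_label=condition_label)
    return trace, truth


def generate_dataset(
    cfg: GaitSimConfig,
    n_ff: int = 0,
    n_mf: int = 0,
    n_rf: int = 0,
) -> list[tuple[ForceTrace, GroundTruth]]:
    """Generate a shuffled dataset with the requested per-condition counts.

    Each record's FSA is drawn from the requested condition's Gaussian, but
    the ground-truth class is re-derived from the drawn FSA via the
    Altman-Davis cut-offs, so a draw near a class boundary may carry a label
    different from its condition.  The whole dataset is reproducible from
    ``cfg.seed`` alone.
    """
    counts = {"FF": n_ff, "MF": n_mf, "RF": n_rf}
    if any(c < 0 for c in counts.values()):
        raise InputError("per-class counts must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    records: list[tuple[ForceTrace, GroundTruth]] = []
    for label in ("FF", "MF", "RF"):
        n = counts[label]
        if n == 0:
            continue
        angles = sample_fsa(cfg, label, n, rng=rng)
        for fsa in angles:
            records.append(synthesize_trace(fsa, cfg, rng=rng, condition_label=label))
    rng.shuffle(records)  # type: ignore[arg-type]
    return records


def noiseless(cfg: GaitSimConfig) -> GaitSimConfig:
    """Convenience copy of a config with sensor noise switched off."""
    return replace(cfg, noise_sd=0.0)
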
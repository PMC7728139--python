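"""Gait event detection from the insole loading rate.

Initial contact (IC) is the first frame in which the loading rate of the total
insole force exceeds +1500 N/s; toe off (TO) is the last frame in which it
drops below -1500 N/s.  Events are frame-resolution: no sub-sample
interpolation is attempted, matching the 100 Hz frame language of the insole
validation literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError, NoStanceError
from .simulate import ForceTrace

__all__ = ["EventConfig", "StanceWindow", "loading_rate", "segment_stance"]


@dataclass(frozen=True)
class EventConfig:
    """Loading-rate thresholds (N/s) applied to the total force."""

    ic_threshold: float = 1500.0
    to_threshold: float = -1500.0

    def __post_init__(self) -> None:
        if not (self.ic_threshold > 0 > self.to_threshold):
            raise ConfigError("need ic_threshold > 0 > to_threshold")


@dataclass(frozen=True)
class StanceWindow:
    """IC/TO sample indices delimiting one stance phase (inclusive)."""

    ic_index: int
    to_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.ic_index < self.to_index):
            raise InputError("need 0 <= ic_index < to_index")

    @property
    def n_samples(self) -> int:
        return self.to_index - self.ic_index + 1


def loading_rate(trace: ForceTrace) -> np.ndarray:
    """Backward first difference of the total force, scaled to N/s.

    The first element has no predecessor and is returned as NaN.
    """
    if len(trace) < 2:
        raise InputError("loading rate needs at least 2 samples")
    rate = np.empty(len(trace))
    rate[0] = np.nan
    rate[1:] = np.diff(trace.force_total) * trace.sampling_rate
    return rate


def segment_stance(trace: ForceTrace, cfg: EventConfig | None = None) -> StanceWindow:
    """Delimit the stance phase by loading-rate threshold crossings.

    Raises
    ------
    NoStanceError
        If either threshold is never crossed, or the crossings are out of
        order (TO not after IC).
    """
    if cfg is None:
        cfg = EventConfig()
    rate = loading_rate(trace)
    above = np.flatnonzero(rate > cfg.ic_threshold)
    below = np.flatnonzero(rate < cfg.to_threshold)
    if above.size == 0 or below.size == 0:
        raise NoStanceError(
            "no stance detected: loading rate never crossed "
            f"{cfg.ic_threshold:+.0f}/{cfg.to_threshold:+.0f} N/s "
            f"(max {np.nanmax(rate):.0f}, min {np.nanmin(rate):.0f} N/s)"
        )
    ic = int(above[0])
    to = int(below[-1])
    if to <= ic:
        raise NoStanceError(
            f"no stance detected: TO candidate (frame {to}) not after IC (frame {ic})"
        )
    return StanceWindow(ic_index=ic, to_index=to)
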
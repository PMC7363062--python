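"""Gait event detection from insole foot-switch (FSR) channels.

Heel-strike is the upward crossing of the heel switch through a relative
threshold of its dynamic range; toe-off is the downward crossing of the
toe switch through the same relative level.  A hysteresis band rejects
chatter around the threshold and a refractory gap rejects double
triggers; crossing times are linearly interpolated between samples, so
detection is sub-sample consistent and invariant to affine rescaling of
the FSR trace.

Stance is the interval heel-strike -> ipsilateral toe-off; swing is
toe-off -> next ipsilateral heel-strike (standard gait convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_model import SampledSignal

__all__ = ["GaitEvents", "GaitCycle", "detect_events", "segment_cycles", "events_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitEvents:
    """Heel-strike and toe-off times (seconds) for one foot."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    foot: str = "left"

    def __post_init__(self) -> None:
        for name in ("heel_strikes", "toe_offs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, arr)

    @property
    def n_events(self) -> int:
        return self.heel_strikes.size + self.toe_offs.size


@dataclass(frozen=True)
class GaitCycle:
    """One stance+swing cycle: [heel_strike, toe_off) then [toe_off, next heel_strike)."""

    stance: tuple[float, float]
    swing: tuple[float, float]
    foot: str = "left"

    def __post_init__(self) -> None:
        (s0, s1), (w0, w1) = self.stance, self.swing
        if not (s1 == w0):
            raise ValueError("stance.end must equal swing.start")
        if not (s1 > s0 and w1 > w0):
            raise ValueError("stance and swing durations must be > 0")

    @property
    def start(self) -> float:
        return self.stance[0]

    @property
    def end(self) -> float:
        return self.swing[1]

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def stance_fraction(self) -> float:
        return (self.stance[1] - self.stance[0]) / self.duration


def _cross_times(
    x: np.ndarray, fs: float, level: float, arm_level: float, rising: bool, min_gap: float
) -> np.ndarray:
    """Interpolated threshold crossings with hysteresis + refractory gap.

    The detector arms when the signal is beyond ``arm_level`` on the far
    side of the threshold and fires at the first crossing of ``level`` in
    the requested direction; crossings within ``min_gap`` of the last
    accepted one are discarded.
    """
    if not rising:
        x, level, arm_level = -x, -level, -arm_level
    times: list[float] = []
    armed = x[0] <= arm_level
    for i in range(1, x.size):
        if x[i] <= arm_level:
            armed = True
        elif armed and x[i - 1] < level <= x[i]:
            t = (i - 1 + (level - x[i - 1]) / (x[i] - x[i - 1])) / fs
            if not times or t - times[-1] >= min_gap:
                times.append(t)
            armed = False
    return np.asarray(times)


def detect_events(
    heel: SampledSignal,
    toe: SampledSignal,
    rel_threshold: float = 0.5,
    min_gap: float = 0.2,
    hysteresis: float = 0.1,
    foot: str = "left",
) -> GaitEvents:
    """Detect heel-strikes (heel channel) and toe-offs (toe channel).

    Parameters
    ----------
    heel, toe : SampledSignal
        Foot-switch traces of the same foot; same fs and length.
    rel_threshold : float
        Crossing level as a fraction of each channel's (max - min) range,
        in (0, 1).
    min_gap : float
        Refractory period in seconds between accepted events of one kind.
    hysteresis : float
        Re-arming band half-width as a fraction of range.

    Returns
    -------
    GaitEvents
        Interpolated event times; empty (with a logged warning) when a
        channel is flat.
    """
    if not (0 < rel_threshold < 1):
        raise ValueError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    if not (min_gap > 0):
        raise ValueError("min_gap must be > 0")
    if heel.fs != toe.fs or len(heel) != len(toe):
        raise ValueError("heel and toe channels must share fs and length")

    def channel_events(sig: SampledSignal, rising: bool) -> np.ndarray:
        x = sig.samples
        lo, hi = float(np.min(x)), float(np.max(x))
        rng = hi - lo
        if rng <= 0:
            log.warning("flat %s channel %r: no events detected",
                        "heel" if rising else "toe", sig.label)
            return np.empty(0)
        level = lo + rel_threshold * rng
        arm = level - hysteresis * rng if rising else level + hysteresis * rng
        return _cross_times(x, sig.fs, level, arm, rising, min_gap)

    return GaitEvents(
        heel_strikes=channel_events(heel, rising=True),
        toe_offs=channel_events(toe, rising=False),
        foot=foot,
    )


def segment_cycles(events: GaitEvents) -> list[GaitCycle]:
    """Build complete gait cycles from alternating heel-strike/toe-off events.

    One cycle per (heel-strike, following toe-off, following heel-strike)
    triple; leading/trailing fragments without all three events are
    dropped.  Fewer than two heel-strikes yields an empty list.
    """
    hs = events.heel_strikes
    to = events.toe_offs
    cycles: list[GaitCycle] = []
    for k in range(hs.size - 1):
        t0, t1 = hs[k], hs[k + 1]
        inside = to[(to > t0) & (to < t1)]
        if inside.size == 0:
            continue
        toff = float(inside[0])
        cycles.append(
            GaitCycle(stance=(float(t0), toff), swing=(toff, float(t1)), foot=events.foot)
        )
    return cycles


def events_table(events: GaitEvents) -> pd.DataFrame:
    """Tidy event table (columns: foot, event_type, time_s), CSV-ready."""
    rows = [(events.foot, "heel_strike", t) for t in events.heel_strikes]
    rows += [(events.foot, "toe_off", t) for t in events.toe_offs]
    df = pd.DataFrame(rows, columns=["foot", "event_type", "time_s"])
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)
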
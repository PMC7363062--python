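"""ECG-derived heart rate, Physiological Cost Index, and exercise zones.

R peaks are located with the classic QRS energy chain: 5-15 Hz
band-pass, differentiation, squaring, 150 ms moving-window integration,
then an adaptive signal/noise threshold with a refractory period; each
accepted detection is refined to the maximum of the band-passed ECG so
beat times stay aligned to the R wave.  Inter-beat (R-R) intervals
outside the physiologic 0.25-3 s band (20-240 bpm) are treated as
detector glitches and dropped.

The Physiological Cost Index summarizes the heart-rate cost of walking:

    PCI = (HR_WALK - HR_REST) / walking speed      [beats per metre]

with speed in m/min so PCI carries its conventional beats/m unit.

The exercise threshold zone keeps treadmill work between 50% and 80% of
the age-predicted maximum heart rate HR_MAX = 220 - age; for patients on
beta-blocker (heart-rate-lowering) medication HR_MAX is first scaled by
0.85.  The lower bound is inclusive and the upper bound exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_model import SampledSignal

__all__ = [
    "HrSeries",
    "PciInputs",
    "ThresholdZone",
    "detect_r_peaks",
    "mean_hr",
    "pci",
    "hr_max",
    "threshold_zone",
    "mps_to_m_per_min",
    "beat_table",
]

log = logging.getLogger(__name__)

RR_MIN = 0.25  # s (240 bpm)
RR_MAX = 3.0   # s (20 bpm)


@dataclass(frozen=True)
class HrSeries:
    """Detected beat times with R-R intervals and instantaneous HR."""

    beat_times: np.ndarray  # s
    rr: np.ndarray          # s, successive differences (len = beats - 1)
    hr_inst: np.ndarray     # 60 / rr, beats/min

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ValueError("beat_times must be strictly increasing")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rr", np.asarray(self.rr, dtype=float))
        object.__setattr__(self, "hr_inst", np.asarray(self.hr_inst, dtype=float))

    @classmethod
    def from_beats(cls, beat_times: np.ndarray) -> "HrSeries":
        bt = np.asarray(beat_times, dtype=float)
        rr = np.diff(bt)
        return cls(beat_times=bt, rr=rr, hr_inst=60.0 / rr if rr.size else rr)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


@dataclass(frozen=True)
class PciInputs:
    """Inputs to the Physiological Cost Index."""

    hr_walk: float        # beats/min during the walk
    hr_rest: float        # beats/min at rest
    walking_speed: float  # m/min

    def __post_init__(self) -> None:
        if self.hr_walk <= 0 or self.hr_rest <= 0:
            raise ValueError("heart rates must be > 0")
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be > 0 m/min")


@dataclass(frozen=True)
class ThresholdZone:
    """Heart-rate exercise zone [lower, upper) in beats/min."""

    lower: float
    upper: float
    hr_max: float
    case: str  # "standard" | "beta_blocker"

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper < self.hr_max):
            raise ValueError(
                f"need 0 < lower < upper < hr_max, got "
                f"({self.lower}, {self.upper}, {self.hr_max})"
            )

    def contains(self, hr: float) -> bool:
        """Lower bound inclusive, upper bound exclusive."""
        return self.lower <= hr < self.upper


def detect_r_peaks(ecg: SampledSignal) -> HrSeries:
    """Detect R peaks and return the beat series.

    Needs at least 2 s of signal.  Returns an empty series (with a
    logged warning) when no convincing peaks exist, e.g. a flat trace.
    """
    fs = ecg.fs
    if ecg.duration < 2.0:
        raise ValueError(f"need >= 2 s of ECG, got {ecg.duration:.2f} s")
    x = ecg.samples
    if np.ptp(x) == 0:
        log.warning("flat ECG channel: no beats detected")
        return HrSeries.from_beats(np.empty(0))

    sos = sps.butter(2, (5.0, 15.0), btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    w = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refractory = int(round(RR_MIN * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        log.warning("no integrated-energy peaks: no beats detected")
        return HrSeries.from_beats(np.empty(0))

    # adaptive signal/noise threshold, seeded on the first 2 s
    init = mwi[: int(2 * fs)]
    spki = float(np.max(init)) * 0.5
    npki = float(np.mean(init)) * 0.5
    accepted: list[int] = []
    for i in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[i] > thr:
            accepted.append(i)
            spki = 0.125 * mwi[i] + 0.875 * spki
        else:
            npki = 0.125 * mwi[i] + 0.875 * npki
    if not accepted:
        log.warning("no peaks above adaptive threshold: no beats detected")
        return HrSeries.from_beats(np.empty(0))

    # refine each detection to the R wave on the band-passed trace
    half = int(round(0.100 * fs))
    beats = []
    for i in accepted:
        lo, hi = max(i - half, 0), min(i + half + 1, x.size)
        beats.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    beat_idx = np.unique(beats)

    # physiologic R-R gating: drop beats that create implausible intervals
    times = beat_idx / fs
    kept = [times[0]]
    for t in times[1:]:
        dt = t - kept[-1]
        if dt < RR_MIN:
            continue  # glitch / double detection
        kept.append(t)
    times = np.asarray(kept)
    rr = np.diff(times)
    ok = (rr > RR_MIN) & (rr < RR_MAX)
    if rr.size and not np.all(ok):
        log.warning("dropped %d beats outside physiologic R-R gates", int((~ok).sum()))
        # rebuild by keeping beats that begin plausible intervals
        times = np.concatenate([[times[0]], times[1:][ok]])
    return HrSeries.from_beats(times)


def mean_hr(series: HrSeries, window: tuple[float, float]) -> float:
    """Mean heart rate over a time window, beats/min.

    Defined as ``60 * (beat count - 1) / elapsed`` where ``elapsed`` is
    the span from the first to the last beat inside the window; needs at
    least two beats inside the window.
    """
    t0, t1 = window
    inside = series.beat_times[(series.beat_times >= t0) & (series.beat_times <= t1)]
    if inside.size < 2:
        raise ValueError(
            f"need >= 2 beats inside window ({t0}, {t1}); found {inside.size}"
        )
    return 60.0 * (inside.size - 1) / (inside[-1] - inside[0])


def pci(inputs: PciInputs) -> float:
    """Physiological Cost Index, beats per metre.

    ``(hr_walk - hr_rest) / walking_speed`` with speed in m/min.  A
    negative value (walking HR below resting HR) is returned as-is with
    a logged flag.
    """
    value = (inputs.hr_walk - inputs.hr_rest) / inputs.walking_speed
    if value < 0:
        log.warning("PCI negative (%.4f): hr_walk below hr_rest", value)
    return value


def mps_to_m_per_min(speed_mps: float) -> float:
    """Convert a walking speed from m/s to m/min."""
    return speed_mps * 60.0


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate, 220 - age (beats/min)."""
    if not (0 < age < 130):
        raise ValueError(f"age {age} outside (0, 130) years")
    return 220.0 - age


def threshold_zone(age: float, beta_blocker: bool = False) -> ThresholdZone:
    """Exercise threshold zone [0.5*H, 0.8*H) with H the (possibly
    medication-scaled) maximum heart rate."""
    hmax = hr_max(age)
    effective = 0.85 * hmax if beta_blocker else hmax
    return ThresholdZone(
        lower=0.5 * effective,
        upper=0.8 * effective,
        hr_max=hmax,
        case="beta_blocker" if beta_blocker else "standard",
    )


def beat_table(series: HrSeries) -> pd.DataFrame:
    """Tidy beat table (beat_time_s, rr_s, hr_bpm), CSV-ready."""
    n = series.n_beats
    rr = np.concatenate([[np.nan], series.rr]) if n else np.empty(0)
    hr = np.concatenate([[np.nan], series.hr_inst]) if n else np.empty(0)
    return pd.DataFrame(
        {"beat_time_s": series.beat_times, "rr_s": rr, "hr_bpm": hr}
    )
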
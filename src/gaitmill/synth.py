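"""Synthetic physiological signal generators with ground truth.

Every generator here is deterministic given (parameters, seed) and
returns the ground truth it used (event schedules, R-R intervals,
injected effects) alongside the signal, so each downstream detector and
estimator has an independent oracle to be tested against.

What is emulated
----------------
* **Gait / FSR** — square-like heel and toe switch traces from a
  nominal cadence with optional Gaussian timing jitter.
* **sEMG** — gated band-limited Gaussian noise, the standard surrogate
  for the interference EMG pattern: gastrocnemius lateralis (GL) bursts
  in stance, tibialis anterior (TA) in swing plus early stance, with
  raised-cosine onset/offset ramps and a broadband floor at 2% of the
  burst amplitude.
* **ECG** — a fixed PQRST template (1 mV R peak) placed at cumulative
  R-R times.
* **Virtual patient** — first-order heart-rate dynamics with a linear
  steady-state HR-speed relation, per-trial adaptation drift and
  optional noise, for closed-loop controller tests.
* **Cohorts** — paired pre/post sessions per participant pushed through
  the full detection + feature pipeline, with known multiplicative
  amplitude and spectral-shift effects injected in the "post" session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import ClassVar

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import cardio, controller, emg_features, gait_events
from .cardio import ThresholdZone
from .gait_events import GaitCycle, GaitEvents
from .signal_model import SampledSignal

__all__ = [
    "GaitSchedule",
    "Burst",
    "EmgBurstSpec",
    "VirtualPatient",
    "CohortEffect",
    "default_burst_spec",
    "gen_gait",
    "gen_emg",
    "gen_ecg",
    "patient_hr",
    "closed_loop",
    "gen_cohort",
    "synth_session",
]


@dataclass(frozen=True)
class GaitSchedule:
    """Nominal gait timing for the FSR generator."""

    cycle_duration: float = 1.2   # s per stride
    stance_fraction: float = 0.6  # fraction of the cycle in stance
    n_cycles: int = 10
    jitter_sd: float = 0.0        # s, Gaussian jitter on each event time
    start: float = 0.0            # s, time of the first heel strike

    def __post_init__(self) -> None:
        if not (0 < self.stance_fraction < 1):
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.jitter_sd < 0 or self.start < 0:
            raise ValueError("jitter_sd and start must be >= 0")


@dataclass(frozen=True)
class Burst:
    """One muscle burst: amplitude (mV std), pass band (Hz), duty cycle."""

    amplitude: float
    band: tuple[float, float]
    duty: float = 0.8
    align: str = "center"  # "center" | "start" within the phase

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 < self.duty <= 1):
            raise ValueError("duty must be in (0, 1]")
        if self.align not in ("center", "start"):
            raise ValueError("align must be 'center' or 'start'")


@dataclass(frozen=True)
class EmgBurstSpec:
    """Burst parameters keyed by (muscle, phase).

    Encodes the activation pattern of healthy-side gait: GL drives
    push-off in stance, TA dorsiflexes in swing (for toe clearance) and
    decelerates foot drop in early stance.
    """

    entries: dict[tuple[str, str], Burst] = field(default_factory=dict)

    def for_muscle(self, muscle: str) -> dict[str, Burst]:
        return {phase: b for (m, phase), b in self.entries.items() if m == muscle}

    def scaled(self, muscle: str, amplitude_factor: float = 1.0,
               freq_factor: float = 1.0) -> "EmgBurstSpec":
        """Copy with one muscle's amplitudes and band edges multiplied."""
        out = dict(self.entries)
        for key, b in self.entries.items():
            if key[0] == muscle:
                out[key] = replace(
                    b,
                    amplitude=b.amplitude * amplitude_factor,
                    band=(b.band[0] * freq_factor, b.band[1] * freq_factor),
                )
        return EmgBurstSpec(out)


def default_burst_spec() -> EmgBurstSpec:
    """GL stance-dominant, TA swing-dominant with an early-stance burst."""
    return EmgBurstSpec(
        {
            ("GL", "stance"): Burst(amplitude=1.0, band=(60.0, 150.0), duty=0.8),
            ("TA", "swing"): Burst(amplitude=1.0, band=(40.0, 120.0), duty=0.8),
            ("TA", "stance"): Burst(amplitude=0.5, band=(40.0, 120.0),
                                    duty=0.25, align="start"),
        }
    )


@dataclass(frozen=True)
class VirtualPatient:
    """First-order HR dynamics with linear steady-state HR-speed relation.

    Steady state ``HR_ss(v) = hr_rest + gain * v``; trial-to-trial update
    over the trial length T (60 s), with trials numbered t = 1, 2, ...:

        HR_t = HR_{t-1} + (HR_ss(v_t) - t * adaptation - HR_{t-1})
               * (1 - exp(-T/tau)) + noise,

    floored at ``hr_rest``.  ``adaptation`` models within-session
    cardiovascular economization: the HR the same load settles to drops
    by this many bpm per completed trial, so at constant load the trial
    HR series decreases once the first-order transient has died away —
    exactly the condition under which the speed controller offers a
    higher challenge.
    """

    hr_rest: float = 70.0     # bpm
    gain: float = 0.5         # bpm per (m/min)
    tau: float = 30.0         # s, first-order time constant
    adaptation: float = 0.0   # bpm per trial at constant load
    noise_sd: float = 0.0     # bpm

    TRIAL_LENGTH: ClassVar[float] = 60.0  # s per task trial

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.hr_rest <= 0:
            raise ValueError("tau and hr_rest must be > 0")

    def hr_ss(self, speed: float) -> float:
        return self.hr_rest + self.gain * speed

    def step(
        self,
        hr_prev: float,
        speed: float,
        rng: np.random.Generator,
        trial: int = 1,
    ) -> float:
        """Mean HR of trial number ``trial`` (1-based) at ``speed``."""
        alpha = 1.0 - np.exp(-self.TRIAL_LENGTH / self.tau)
        target = self.hr_ss(speed) - trial * self.adaptation
        hr = hr_prev + (target - hr_prev) * alpha
        if self.noise_sd > 0:
            hr += rng.normal(0.0, self.noise_sd)
        return max(hr, self.hr_rest)


# ------------------------------------------------------------------ gait

def gen_gait(
    schedule: GaitSchedule,
    fs: float = 1000.0,
    seed: int | None = 0,
    noise_sd: float = 0.0,
) -> tuple[SampledSignal, SampledSignal, GaitEvents]:
    """Generate heel/toe FSR traces plus the ground-truth event schedule.

    Heel contact spans [heel-strike, 85% of stance]; toe contact spans
    [15% of stance, toe-off] — so heel-strike is the heel channel's
    rising edge and toe-off the toe channel's falling edge.  ``noise_sd``
    adds white Gaussian measurement noise on top of the 0/1 traces.
    """
    rng = np.random.default_rng(seed)
    hs = schedule.start + schedule.cycle_duration * np.arange(schedule.n_cycles)
    stance = schedule.stance_fraction * schedule.cycle_duration
    to = hs + stance
    if schedule.jitter_sd > 0:
        hs = hs + rng.normal(0.0, schedule.jitter_sd, hs.size)
        to = to + rng.normal(0.0, schedule.jitter_sd, to.size)
        hs.sort(); to.sort()

    duration = schedule.start + schedule.cycle_duration * schedule.n_cycles
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs
    heel = np.zeros(n)
    toe = np.zeros(n)
    for k in range(schedule.n_cycles):
        span = to[k] - hs[k]
        heel[(t >= hs[k]) & (t < hs[k] + 0.85 * span)] = 1.0
        toe[(t >= hs[k] + 0.15 * span) & (t < to[k])] = 1.0
    if noise_sd > 0:
        heel = heel + rng.normal(0.0, noise_sd, n)
        toe = toe + rng.normal(0.0, noise_sd, n)
    events = GaitEvents(heel_strikes=hs, toe_offs=to, foot="left")
    return (
        SampledSignal(heel, fs, "FSR_heel_L"),
        SampledSignal(toe, fs, "FSR_toe_L"),
        events,
    )


# ------------------------------------------------------------------- EMG

def _phase_intervals(events: GaitEvents) -> dict[str, list[tuple[float, float]]]:
    cycles = gait_events.segment_cycles(events)
    return {
        "stance": [c.stance for c in cycles],
        "swing": [c.swing for c in cycles],
    }


def _gate(t: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    """Raised-cosine-gated unit window on [start, stop]."""
    g = np.zeros_like(t)
    core = (t >= start + ramp) & (t <= stop - ramp)
    g[core] = 1.0
    rise = (t >= start) & (t < start + ramp)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / ramp))
    fall = (t > stop - ramp) & (t <= stop)
    g[fall] = 0.5 * (1 - np.cos(np.pi * (stop - t[fall]) / ramp))
    return g


def gen_emg(
    events: GaitEvents,
    spec: EmgBurstSpec,
    fs: float = 1000.0,
    seed: int | None = 0,
    muscle: str = "GL",
    label: str = "",
    n_samples: int | None = None,
) -> SampledSignal:
    """Phase-locked sEMG surrogate for one muscle channel.

    Band-limited Gaussian noise bursts (unit-std normalized, scaled by
    the burst amplitude) gated by the muscle's phase intervals with 10%
    raised-cosine ramps, plus a broadband floor at 2% of the largest
    burst amplitude (or of 1 mV when all amplitudes are zero).
    """
    bursts = spec.for_muscle(muscle)
    for b in bursts.values():
        if not (0 < b.band[0] < b.band[1] < fs / 2):
            raise ValueError(f"band {b.band} outside (0, {fs / 2}) Hz")
    intervals = _phase_intervals(events)
    t_end = float(max(events.heel_strikes[-1], events.toe_offs[-1])) if events.n_events else 1.0
    n = n_samples if n_samples is not None else int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    amp_ref = max([b.amplitude for b in bursts.values()] + [0.0])
    floor_sd = 0.02 * (amp_ref if amp_ref > 0 else 1.0)
    x = rng.normal(0.0, floor_sd, n)

    for phase, b in bursts.items():
        if b.amplitude <= 0:
            continue
        carrier = rng.normal(0.0, 1.0, n)
        sos = sps.butter(4, b.band, btype="bandpass", fs=fs, output="sos")
        carrier = sps.sosfiltfilt(sos, carrier)
        carrier /= max(np.std(carrier), 1e-30)
        gate = np.zeros(n)
        for (p0, p1) in intervals.get(phase, []):
            dur = (p1 - p0) * b.duty
            if b.align == "center":
                b0 = p0 + ((p1 - p0) - dur) / 2
            else:
                b0 = p0
            ramp = 0.1 * dur
            gate = np.maximum(gate, _gate(t, b0, b0 + dur, ramp))
        x = x + b.amplitude * gate * carrier
    return SampledSignal(x, fs, label or f"{muscle}_synth")


# ------------------------------------------------------------------- ECG

def _pqrst_template(t: np.ndarray) -> np.ndarray:
    """Sum-of-Gaussians PQRST morphology, R peak 1 mV at t = 0."""
    waves = [  # (amplitude mV, center s, width s)
        (0.15, -0.20, 0.025),
        (-0.10, -0.030, 0.010),
        (1.00, 0.000, 0.012),
        (-0.25, 0.030, 0.010),
        (0.30, 0.220, 0.050),
    ]
    y = np.zeros_like(t)
    for a, mu, sd in waves:
        y += a * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return y


def gen_ecg(rr_schedule, fs: float = 1000.0) -> tuple[SampledSignal, np.ndarray]:
    """Template ECG with beats at cumulative R-R times.

    Returns the trace and the ground-truth R-peak times.  An empty
    schedule yields a flat 2 s baseline.
    """
    rr = np.asarray(list(rr_schedule), dtype=float)
    if rr.size and not np.all((rr > cardio.RR_MIN) & (rr < cardio.RR_MAX)):
        raise ValueError(f"all R-R intervals must lie in ({cardio.RR_MIN}, {cardio.RR_MAX}) s")
    beat_times = np.cumsum(rr)
    duration = (beat_times[-1] + 0.5) if rr.size else 2.0
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs
    x = np.zeros(n)
    half = 0.35  # s of template support on either side of R
    for bt in beat_times:
        i0 = max(int((bt - half) * fs), 0)
        i1 = min(int((bt + half + 0.15) * fs), n)
        x[i0:i1] += _pqrst_template(t[i0:i1] - bt)
    return SampledSignal(x, fs, "ECG"), beat_times


# -------------------------------------------------------- virtual patient

def patient_hr(
    patient: VirtualPatient, speed_trace, seed: int | None = 0
) -> np.ndarray:
    """Per-trial mean HR of the virtual patient over a fixed speed trace."""
    rng = np.random.default_rng(seed)
    hr = patient.hr_rest
    out = []
    for t, v in enumerate(speed_trace, start=1):
        hr = patient.step(hr, float(v), rng, trial=t)
        out.append(hr)
    return np.asarray(out)


def closed_loop(
    patient: VirtualPatient,
    zone: ThresholdZone,
    speed0: float,
    increment: float = controller.DEFAULT_INCREMENT,
    max_trials: int = controller.DEFAULT_MAX_TRIALS,
    seed: int | None = 0,
) -> list[dict]:
    """Run the speed controller against the virtual patient.

    Each trial: the patient walks one minute at the current speed, the
    resulting mean HR drives the controller's maintain/increase/
    terminate decision for the next trial.  Returns the session trace
    (same record shape as :func:`gaitmill.controller.run_session`).
    """
    rng = np.random.default_rng(seed)
    state = controller.ControllerState(zone=zone, speed=speed0, increment=increment)
    hr = patient.hr_rest
    trace: list[dict] = []
    for t in range(1, max_trials + 1):
        speed_during = state.speed
        hr = patient.step(hr, speed_during, rng, trial=t)
        state, outcome = controller.step_trial(state, hr)
        trace.append(
            {
                "trial": state.trial_index,
                "mean_hr_bpm": float(hr),
                "speed_m_per_min": speed_during,
                "action": outcome.action,
                "feedback": outcome.feedback,
            }
        )
        if state.status == "terminated":
            break
    return trace


# ----------------------------------------------------------------- cohort

@dataclass(frozen=True)
class CohortEffect:
    """Multiplicative pre->post effects keyed by (muscle, side).

    ``amplitude`` scales burst amplitudes (raises MAV/RMS), ``freq_shift``
    scales band edges (shifts MF/MDF).  Missing keys mean no change.
    """

    amplitude: dict[tuple[str, str], float] = field(default_factory=dict)
    freq_shift: dict[tuple[str, str], float] = field(default_factory=dict)

    def factors(self, muscle: str, side: str) -> tuple[float, float]:
        return (
            self.amplitude.get((muscle, side), 1.0),
            self.freq_shift.get((muscle, side), 1.0),
        )


def synth_session(
    spec_by_side: dict[str, EmgBurstSpec],
    schedule: GaitSchedule,
    fs: float = 1000.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """One synthetic session through the full detection + feature pipeline.

    Generates FSR traces, detects events and cycles, synthesizes and
    preprocesses GL/TA channels for both sides, and returns the long
    feature table (muscle, side, phase, mav, rms, mf, mdf, n_cycles).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kids = ss.spawn(5)
    heel, toe, _truth = gen_gait(schedule, fs=fs, seed=kids[0])
    ev = gait_events.detect_events(heel, toe)
    cycles = gait_events.segment_cycles(ev)
    feats = emg_features.PhaseFeatureSet()
    for i, side in enumerate(("affected", "unaffected")):
        for j, muscle in enumerate(("GL", "TA")):
            raw = gen_emg(ev, spec_by_side[side], fs=fs,
                          seed=kids[1 + 2 * i + j], muscle=muscle)
            clean = emg_features.preprocess(raw)
            feats.update(
                emg_features.phase_features(clean, cycles, muscle=muscle, side=side)
            )
    return feats.to_frame().drop(columns=["session_id"])


def gen_cohort(
    n_participants: int = 9,
    pre_spec: EmgBurstSpec | None = None,
    effect: CohortEffect | None = None,
    seed: int | None = 0,
    fs: float = 1000.0,
    schedule: GaitSchedule | None = None,
    between_subject_sd: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired pre/post feature tables for a synthetic cohort.

    Each participant gets a lognormal between-subject amplitude factor
    and a mild band-edge factor applied to *both* sessions (the paired
    structure); the post session additionally carries the injected
    ``effect``.  Session-to-session variability comes from the EMG noise
    realizations themselves.

    Returns ``(pre_table, post_table, truth)`` where the tables are long
    DataFrames with a ``participant`` column and ``truth`` records the
    injected effect.
    """
    if n_participants < 2:
        raise ValueError("need n_participants >= 2")
    pre_spec = pre_spec or default_burst_spec()
    effect = effect or CohortEffect()
    schedule = schedule or GaitSchedule(cycle_duration=1.2, stance_fraction=0.6,
                                        n_cycles=10, jitter_sd=0.01, start=0.7)
    root = np.random.SeedSequence(seed)
    pre_rows, post_rows = [], []
    for p, pseq in enumerate(root.spawn(n_participants)):
        subj_rng = np.random.default_rng(pseq)
        base: dict[str, EmgBurstSpec] = {}
        for side in ("affected", "unaffected"):
            s = pre_spec
            for muscle in ("GL", "TA"):
                amp = float(np.exp(subj_rng.normal(0.0, between_subject_sd)))
                frq = float(np.exp(subj_rng.normal(0.0, 0.05)))
                s = s.scaled(muscle, amplitude_factor=amp, freq_factor=frq)
            base[side] = s
        post = {
            side: _apply_effect(base[side], effect, side)
            for side in ("affected", "unaffected")
        }
        s_pre, s_post = pseq.spawn(2)
        tab_pre = synth_session(base, schedule, fs=fs, seed=s_pre)
        tab_post = synth_session(post, schedule, fs=fs, seed=s_post)
        tab_pre.insert(0, "participant", p)
        tab_post.insert(0, "participant", p)
        pre_rows.append(tab_pre)
        post_rows.append(tab_post)
    truth = {"effect": effect, "n_participants": n_participants, "seed": seed}
    return (
        pd.concat(pre_rows, ignore_index=True),
        pd.concat(post_rows, ignore_index=True),
        truth,
    )


def _apply_effect(spec: EmgBurstSpec, effect: CohortEffect, side: str) -> EmgBurstSpec:
    out = spec
    for muscle in ("GL", "TA"):
        amp, frq = effect.factors(muscle, side)
        if amp != 1.0 or frq != 1.0:
            out = out.scaled(muscle, amplitude_factor=amp, freq_factor=frq)
    return out
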
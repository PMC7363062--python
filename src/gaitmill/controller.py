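"""Adaptive treadmill speed-switching controller.

A deterministic state machine over per-trial mean walking heart rates.
After each one-minute trial the controller compares the trial's mean HR
with the previous trial's:

* HR above the zone's upper bound  -> terminate the exercise;
* HR lower than the preceding trial's -> the participant has spare
  cardiovascular capacity: increase the treadmill speed by one
  increment (raising exercise intensity);
* otherwise -> maintain the current speed.

When an increase was applied entering a trial, the trial's outcome also
carries motivational feedback: the encouraging message if the
participant coped (HR stayed at or below the upper bound), the
consolatory one otherwise.  The zone's lower bound plays no role in
switching; it is carried for logging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .cardio import ThresholdZone

__all__ = [
    "ControllerState",
    "TrialOutcome",
    "step_trial",
    "run_session",
    "trace_table",
    "FEEDBACK_COPED",
    "FEEDBACK_TRY",
    "DEFAULT_INCREMENT",
    "DEFAULT_MAX_TRIALS",
]

FEEDBACK_COPED = "You are doing great, Keep it up"
FEEDBACK_TRY = "Keep trying, You can do better"

DEFAULT_INCREMENT = 3.0  # m/min (0.05 m/s) per speed increase
DEFAULT_MAX_TRIALS = 10  # one-minute task trials per session


@dataclass(frozen=True)
class ControllerState:
    """Controller state between trials."""

    zone: ThresholdZone
    speed: float                       # m/min
    increment: float = DEFAULT_INCREMENT
    prev_trial_hr: float | None = None
    trial_index: int = 0
    status: str = "running"            # "running" | "terminated"
    pending_increase: bool = False     # an increase was applied entering this trial
    deadband: float = 0.0              # bpm; HR must drop by more than this to count

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be > 0 m/min")
        if self.increment <= 0:
            raise ValueError("increment must be > 0 m/min")
        if self.deadband < 0:
            raise ValueError("deadband must be >= 0 bpm")


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one controller step."""

    action: str            # "increase" | "maintain" | "terminate"
    new_speed: float       # m/min entering the next trial
    feedback: str | None   # motivational message, if an increase preceded this trial


def step_trial(state: ControllerState, trial_hr: float) -> tuple[ControllerState, TrialOutcome]:
    """Advance the controller by one completed trial.

    Parameters
    ----------
    state : ControllerState
        Must be running.
    trial_hr : float
        Mean walking HR of the just-completed trial, beats/min.
    """
    if state.status != "running":
        raise RuntimeError("cannot step a terminated controller")
    if trial_hr <= 0:
        raise ValueError("trial_hr must be > 0")

    feedback = None
    if state.pending_increase:
        feedback = FEEDBACK_COPED if trial_hr <= state.zone.upper else FEEDBACK_TRY

    if trial_hr > state.zone.upper:
        action, new_speed, status, pending = "terminate", state.speed, "terminated", False
    elif state.prev_trial_hr is not None and trial_hr < state.prev_trial_hr - state.deadband:
        action, new_speed, status, pending = (
            "increase", state.speed + state.increment, "running", True
        )
    else:
        action, new_speed, status, pending = "maintain", state.speed, "running", False

    new_state = replace(
        state,
        speed=new_speed,
        prev_trial_hr=trial_hr,
        trial_index=state.trial_index + 1,
        status=status,
        pending_increase=pending,
    )
    return new_state, TrialOutcome(action=action, new_speed=new_speed, feedback=feedback)


def run_session(
    zone: ThresholdZone,
    trial_hrs,
    speed0: float,
    increment: float = DEFAULT_INCREMENT,
    max_trials: int = DEFAULT_MAX_TRIALS,
    deadband: float = 0.0,
) -> list[dict]:
    """Fold :func:`step_trial` over a session's per-trial HR sequence.

    Stops at termination or after ``max_trials`` trials.  Returns one
    record per executed trial with keys ``trial``, ``mean_hr_bpm``,
    ``speed_m_per_min`` (speed during the trial), ``action`` and
    ``feedback``.
    """
    state = ControllerState(zone=zone, speed=speed0, increment=increment, deadband=deadband)
    trace: list[dict] = []
    for hr in list(trial_hrs)[:max_trials]:
        speed_during = state.speed
        state, outcome = step_trial(state, hr)
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


def trace_table(trace: list[dict]) -> pd.DataFrame:
    """Session trace as a DataFrame, CSV-ready."""
    return pd.DataFrame(
        trace,
        columns=["trial", "mean_hr_bpm", "speed_m_per_min", "action", "feedback"],
    )
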
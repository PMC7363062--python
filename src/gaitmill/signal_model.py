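"""Core domain types and session I/O.

A recording session bundles uniformly sampled physiological channels
(surface EMG from gastrocnemius lateralis and tibialis anterior of both
legs, a single-lead ECG, and heel/toe foot-switch traces) on one shared
time base, together with participant metadata and the ordered one-minute
trial windows of the treadmill exercise.

Time convention: sample ``i`` of a channel occurs at ``t = i / fs``
seconds (0-based); every event timestamp downstream is expressed in
seconds on this axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_LABELS",
    "SampledSignal",
    "ParticipantMeta",
    "Session",
    "SessionFormatError",
    "read_session",
    "write_session",
    "load_config",
]

#: Channel names understood by the pipeline.  ``GL``/``TA`` are the calf
#: (plantarflexor) and shin (dorsiflexor) muscles; ``aff``/``unaff`` the
#: paretic and non-paretic side; FSR channels are the insole foot switches.
CANONICAL_LABELS = (
    "GL_aff", "GL_unaff", "TA_aff", "TA_unaff",
    "ECG",
    "FSR_heel_L", "FSR_heel_R", "FSR_toe_L", "FSR_toe_R",
)

DEFAULT_FS = 1000.0  # Hz


class SessionFormatError(ValueError):
    """Raised for malformed session files or violated container invariants."""


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled channel.

    Parameters
    ----------
    samples : array-like of float
        Signal values; mV for sEMG/ECG, normalized 0-1 for FSR traces.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str
        Channel name (see :data:`CANONICAL_LABELS`; other labels are
        accepted for ad-hoc use).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise SessionFormatError(
                f"channel {self.label!r}: need a 1-D sequence of length >= 1"
            )
        if not np.all(np.isfinite(arr)):
            raise SessionFormatError(f"channel {self.label!r}: non-finite samples")
        if not (self.fs > 0):
            raise SessionFormatError(f"channel {self.label!r}: fs must be > 0")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based convention)."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SampledSignal":
        """Copy of this channel with new sample values (same fs/label)."""
        return SampledSignal(np.asarray(samples, dtype=float), self.fs, self.label)


@dataclass(frozen=True)
class ParticipantMeta:
    """Participant descriptors consumed by the cardio and controller stages."""

    age: float
    beta_blocker: bool = False
    affected_side: str = "left"
    resting_hr: float = 70.0
    overground_speed: float = 0.0  # m/s, self-selected 10 m walk speed

    def __post_init__(self) -> None:
        if not (0 < self.age < 130):
            raise SessionFormatError(f"age {self.age} outside (0, 130)")
        if self.affected_side not in ("left", "right"):
            raise SessionFormatError("affected_side must be 'left' or 'right'")
        if not (self.resting_hr > 0):
            raise SessionFormatError("resting_hr must be > 0")
        if self.overground_speed < 0:
            raise SessionFormatError("overground_speed must be >= 0")


@dataclass
class Session:
    """A set of channels on one time base plus metadata and trial windows.

    ``trials`` holds ``(start, end)`` windows in seconds — ordered,
    non-overlapping, and inside the record — one per treadmill task trial.
    """

    channels: dict[str, SampledSignal]
    meta: ParticipantMeta | None = None
    trials: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.channels:
            raise SessionFormatError("session has no channels")
        lengths = {len(ch) for ch in self.channels.values()}
        rates = {ch.fs for ch in self.channels.values()}
        if len(lengths) != 1:
            raise SessionFormatError(f"channel length mismatch: {sorted(lengths)}")
        if len(rates) != 1:
            raise SessionFormatError(f"channel fs mismatch: {sorted(rates)}")
        dur = self.duration
        prev_end = 0.0
        for k, (t0, t1) in enumerate(self.trials):
            if not (0 <= t0 < t1 <= dur + 1e-9):
                raise SessionFormatError(
                    f"trial {k} window ({t0}, {t1}) outside record of {dur:.3f} s"
                )
            if t0 < prev_end - 1e-12:
                raise SessionFormatError(f"trial {k} overlaps the previous trial")
            prev_end = t1

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def __getitem__(self, label: str) -> SampledSignal:
        try:
            return self.channels[label]
        except KeyError:
            raise KeyError(
                f"channel {label!r} not in session "
                f"(have {sorted(self.channels)})"
            ) from None


def _meta_from_dict(d: Mapping) -> ParticipantMeta:
    known = {f.name for f in dataclasses.fields(ParticipantMeta)}
    return ParticipantMeta(**{k: v for k, v in d.items() if k in known})


def load_config(path: str | Path) -> dict:
    """Load a YAML session config (fs, channel_map, trials, participant)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SessionFormatError(f"config {path}: expected a YAML mapping")
    return cfg


def read_session(path: str | Path, config: Mapping | None = None) -> Session:
    """Read a session CSV (header row of channel labels, one row per sample).

    ``config`` may carry ``fs`` (default 1000 Hz), ``channel_map``
    (CSV column name -> canonical label), ``trials`` (list of
    ``[start, end]`` second pairs) and ``participant`` (ParticipantMeta
    fields).  Missing optional channels are simply absent from the result.
    """
    config = dict(config or {})
    path = Path(path)
    try:
        df = pd.read_csv(path, header=0)
    except pd.errors.EmptyDataError:
        raise SessionFormatError(f"{path}: empty file") from None
    except pd.errors.ParserError as exc:
        raise SessionFormatError(f"{path}: malformed CSV ({exc})") from None
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise SessionFormatError(f"{path}: no data rows")

    fs = float(config.get("fs", DEFAULT_FS))
    channel_map = config.get("channel_map") or {}
    channels: dict[str, SampledSignal] = {}
    for col in df.columns:
        label = channel_map.get(col, col)
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size and df[col].notna().iloc[bad[0]]:
            raise SessionFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0]}"
            )
        if bad.size:
            raise SessionFormatError(
                f"{path}: missing value in column {col!r} at data row {bad[0]}"
            )
        channels[label] = SampledSignal(values, fs=fs, label=label)

    meta = None
    if config.get("participant"):
        meta = _meta_from_dict(config["participant"])
    trials = [tuple(map(float, w)) for w in config.get("trials", [])]
    return Session(channels=channels, meta=meta, trials=trials)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to CSV, reproducing values to >= 9 significant digits.

    The inverse of :func:`read_session` up to float round-off: a
    write-then-read round trip reproduces every sample to better than
    1e-9 relative.
    """
    session.validate()
    df = pd.DataFrame(
        {label: ch.samples for label, ch in session.channels.items()}
    )
    df.to_csv(path, index=False, float_format="%.12g")
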
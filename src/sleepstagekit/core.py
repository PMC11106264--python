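"""Core containers shared across the toolkit.

Stages follow the AASM five-class alphabet scored per 30-s epoch:
wake (W), NREM stages N1/N2/N3 and REM (R).  Coarser schemes collapse
NREM (three-class: W/NREM/R) or all sleep (two-class: W/SLEEP).
All timestamps are UTC, intervals half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_SECONDS = 30
STAGES = ("W", "N1", "N2", "N3", "R")

THREE_CLASS = ("W", "NREM", "R")
TWO_CLASS = ("W", "SLEEP")

#: deterministic collapse maps from the five-class alphabet
THREE_CLASS_MAP = {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "R": "R"}
TWO_CLASS_MAP = {"W": "W", "N1": "SLEEP", "N2": "SLEEP", "N3": "SLEEP", "R": "SLEEP"}

SCHEME_LABELS = {"five_class": STAGES, "three_class": THREE_CLASS, "two_class": TWO_CLASS}


def _as_time(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts


@dataclass
class RawRecording:
    """A continuous tri-axial acceleration time series (units g)."""

    subject_id: str
    start_time: pd.Timestamp
    sample_rate: float
    samples: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.start_time = _as_time(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sample_rate

    def sample_times(self) -> pd.DatetimeIndex:
        ns = np.round(np.arange(self.n_samples) * 1e9 / self.sample_rate).astype("int64")
        return pd.DatetimeIndex(self.start_time.value + ns)


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels on a contiguous 30-s grid."""

    epoch_start_times: pd.DatetimeIndex
    labels: np.ndarray
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self):
        self.epoch_start_times = pd.DatetimeIndex(self.epoch_start_times)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.epoch_start_times) != len(self.labels):
            raise ValueError("labels and epoch_start_times length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def end_time(self) -> pd.Timestamp:
        return self.epoch_start_times[-1] + pd.Timedelta(seconds=self.epoch_seconds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_start": self.epoch_start_times, "stage": self.labels.astype(str)}
        )


@dataclass
class EpochTensor:
    """Recording regularised to 30-s x 30 Hz x 3-axis windows."""

    epochs: np.ndarray  # (n_epochs, 3, 900)
    epoch_start_times: pd.DatetimeIndex
    wear_mask: np.ndarray  # bool per epoch

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs)
        self.epoch_start_times = pd.DatetimeIndex(self.epoch_start_times)
        self.wear_mask = np.asarray(self.wear_mask, dtype=bool)
        n = self.epochs.shape[0]
        if len(self.epoch_start_times) != n or len(self.wear_mask) != n:
            raise ValueError("inconsistent epoch counts")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class TimeInBedWindow:
    """A detected bed interval, half-open [start, end)."""

    start: pd.Timestamp
    end: pd.Timestamp
    source: str = "detected"

    def __post_init__(self):
        self.start = _as_time(self.start)
        self.end = _as_time(self.end)
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.start + (self.end - self.start) / 2


def read_hypnogram_csv(path) -> Hypnogram:
    df = pd.read_csv(path)
    if not {"epoch_start", "stage"} <= set(df.columns):
        raise ValueError(f"{path}: hypnogram CSV needs columns epoch_start, stage")
    return Hypnogram(pd.DatetimeIndex(pd.to_datetime(df["epoch_start"])), df["stage"].to_numpy())


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    df = hyp.to_frame()
    df["epoch_start"] = df["epoch_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def write_recording_csv(rec: RawRecording, path) -> None:
    """Recording CSV: time (ISO-8601 UTC), x, y, z in g."""
    df = pd.DataFrame(rec.samples, columns=["x", "y", "z"])
    df.insert(0, "time", rec.sample_times().strftime("%Y-%m-%dT%H:%M:%S.%f"))
    df.to_csv(path, index=False, float_format="%.5f")


@dataclass
class QCReport:
    """Recording-level quality-control outcome."""

    subject_id: str = ""
    parse_ok: bool = True
    mean_acc_mg: float | None = None
    calibration_error_mg: float | None = None
    excluded: bool = False
    reasons: list = field(default_factory=list)

    def exclude(self, reason: str) -> None:
        self.excluded = True
        if reason not in self.reasons:
            self.reasons.append(reason)
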
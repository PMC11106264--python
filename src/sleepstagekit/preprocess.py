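"""Raw-accelerometry preprocessing.

The pipeline mirrors the standard large-cohort actigraphy toolchain: the raw
tri-axial signal is resampled to 30 Hz (linear interpolation onto a uniform
grid anchored at the recording start), clipped to +-3 g and divided into
consecutive 30-s windows.  Stationary periods (all three axis standard
deviations < 13 mg) lasting strictly more than 60 min are flagged as
non-wear.  Recordings that cannot be parsed, whose ENMO-style mean exceeds
200 mg ("unrealistic high values"), or that are poorly calibrated are
excluded at quality control.

ENMO = Euclidean norm of the acceleration minus 1 g, floored at zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EPOCH_SECONDS, EpochTensor, QCReport, RawRecording


@dataclass
class PreprocessConfig:
    target_rate: float = 30.0  # Hz
    clip_g: float = 3.0
    epoch_seconds: int = EPOCH_SECONDS
    nonwear_sd_mg: float = 13.0
    nonwear_min_minutes: float = 60.0  # strict: runs must exceed this
    unrealistic_mean_mg: float = 200.0
    calibration_error_mg: float = 30.0  # max mean |norm - 1 g| on stationary epochs

    def __post_init__(self):
        for name in (
            "target_rate",
            "clip_g",
            "epoch_seconds",
            "nonwear_sd_mg",
            "nonwear_min_minutes",
            "unrealistic_mean_mg",
            "calibration_error_mg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.target_rate * self.epoch_seconds))


class ParseError(ValueError):
    pass


def read_recording(path, subject_id: str | None = None):
    """Read a recording CSV (columns time, x, y, z in g).

    Returns ``(RawRecording | None, QCReport)``.  Parse failures (missing
    columns, non-numeric values, non-monotone timestamps, empty file) do not
    raise: the recording is returned as None with ``excluded=True`` and
    reason ``"unparseable"`` so cohort runs can skip bad files, mirroring
    exclusion of data that could not be parsed.
    """
    path = Path(path)
    sid = subject_id or path.stem
    qc = QCReport(subject_id=sid)

    def fail(msg):
        qc.parse_ok = False
        qc.exclude("unparseable")
        qc.reasons.append(msg)
        return None, qc

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # empty file, malformed CSV
        return fail(f"read error: {exc}")
    if not {"time", "x", "y", "z"} <= set(df.columns):
        return fail("missing columns")
    if len(df) == 0:
        return fail("no rows")
    try:
        times = pd.to_datetime(df["time"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        return fail(f"bad timestamps: {exc}")
    xyz = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.isfinite(xyz).all():
        return fail("non-numeric sample values")
    dt = np.diff(times.to_numpy().astype("int64"))
    if len(dt) and (dt <= 0).any():
        return fail("non-monotone timestamps")
    if len(df) < 2:
        return fail("fewer than 2 samples; rate undefined")
    rate = 1e9 / dt.mean()
    rec = RawRecording(sid, times.iloc[0], rate, xyz)
    return rec, qc


def resample_clip(rec: RawRecording, cfg: PreprocessConfig | None = None) -> RawRecording:
    """Resample to the target rate by linear interpolation, then clip.

    The output grid is anchored at ``start_time`` with spacing
    ``1/target_rate``; values outside +-clip_g are saturated at the bound.
    """
    cfg = cfg or PreprocessConfig()
    t_in = np.arange(rec.n_samples) / rec.sample_rate  # uniform grid by contract
    duration = t_in[-1]
    step = 1.0 / cfg.target_rate
    if duration < step:
        raise ValueError("recording shorter than one output sample interval")
    n_out = int(np.floor(duration / step)) + 1
    t_out = np.arange(n_out) * step
    out = np.column_stack([np.interp(t_out, t_in, rec.samples[:, a]) for a in range(3)])
    out = np.clip(out, -cfg.clip_g, cfg.clip_g)
    return RawRecording(rec.subject_id, rec.start_time, cfg.target_rate, out)


def _epoch_axis_sd(rec: RawRecording, cfg: PreprocessConfig) -> np.ndarray:
    """Per-epoch per-axis sd (g), trailing partial epoch dropped. (n_epochs, 3)."""
    spe = cfg.samples_per_epoch
    n_epochs = rec.n_samples // spe
    if n_epochs == 0:
        return np.empty((0, 3))
    x = rec.samples[: n_epochs * spe].reshape(n_epochs, spe, 3)
    return x.std(axis=1, ddof=0)


def detect_nonwear(rec: RawRecording, cfg: PreprocessConfig | None = None) -> list:
    """Non-wear intervals: every axis sd < 13 mg for strictly more than 60 min.

    The sd is computed on the 30-s epoch grid; a contiguous run of
    qualifying epochs is non-wear iff its duration exceeds
    ``nonwear_min_minutes`` (e.g. 121 epochs qualify at the 60-min default,
    120 do not).  Intervals are half-open [start, end) on the epoch grid.
    """
    cfg = cfg or PreprocessConfig()
    sds = _epoch_axis_sd(rec, cfg)
    quiet = (sds < cfg.nonwear_sd_mg / 1000.0).all(axis=1)
    min_epochs = cfg.nonwear_min_minutes * 60.0 / cfg.epoch_seconds
    intervals = []
    i, n = 0, len(quiet)
    while i < n:
        if quiet[i]:
            j = i
            while j < n and quiet[j]:
                j += 1
            if (j - i) > min_epochs:
                start = rec.start_time + pd.Timedelta(seconds=i * cfg.epoch_seconds)
                end = rec.start_time + pd.Timedelta(seconds=j * cfg.epoch_seconds)
                intervals.append((start, end))
            i = j
        else:
            i += 1
    return intervals


def quality_check(rec: RawRecording, cfg: PreprocessConfig | None = None) -> QCReport:
    """Recording-level QC: unrealistic mean acceleration and calibration.

    * ``mean_acc_mg``: ENMO-style mean (vector norm minus 1 g, floored at 0);
      above ``unrealistic_mean_mg`` the recording is excluded.
    * ``calibration_error_mg``: mean |norm - 1 g| over stationary epochs (the
      same epochs the non-wear rule uses); above the configured threshold the
      recording is excluded as poorly calibrated.  With no stationary epochs
      the statistic is undefined: recorded as a reason, not an exclusion.
    """
    cfg = cfg or PreprocessConfig()
    qc = QCReport(subject_id=rec.subject_id)
    norm = np.linalg.norm(rec.samples, axis=1)
    qc.mean_acc_mg = float(np.maximum(norm - 1.0, 0.0).mean() * 1000.0)
    if qc.mean_acc_mg > cfg.unrealistic_mean_mg:
        qc.exclude("unrealistic high values")
    sds = _epoch_axis_sd(rec, cfg)
    quiet = (sds < cfg.nonwear_sd_mg / 1000.0).all(axis=1)
    if quiet.any():
        spe = cfg.samples_per_epoch
        n_epochs = len(quiet)
        en = norm[: n_epochs * spe].reshape(n_epochs, spe)
        qc.calibration_error_mg = float(np.abs(en[quiet] - 1.0).mean() * 1000.0)
        if qc.calibration_error_mg > cfg.calibration_error_mg:
            qc.exclude("poorly calibrated")
    else:
        qc.calibration_error_mg = None
        qc.reasons.append("no stationary epochs; calibration undefined")
    return qc


def epochize(
    rec: RawRecording,
    cfg: PreprocessConfig | None = None,
    nonwear: list | None = None,
) -> EpochTensor:
    """Divide a 30 Hz recording into consecutive 30-s windows (3 x 900).

    The trailing partial window is dropped.  ``wear_mask`` is False on
    epochs intersecting a non-wear interval (detected here unless intervals
    are supplied).
    """
    cfg = cfg or PreprocessConfig()
    if abs(rec.sample_rate - cfg.target_rate) > 1e-3:
        raise ValueError("epochize expects a recording at the target rate")
    spe = cfg.samples_per_epoch
    n_epochs = rec.n_samples // spe
    if n_epochs == 0:
        warnings.warn("recording shorter than one epoch; zero epochs returned")
    x = rec.samples[: n_epochs * spe].reshape(n_epochs, spe, 3)
    epochs = np.ascontiguousarray(x.transpose(0, 2, 1), dtype=np.float32)
    times = pd.DatetimeIndex(
        rec.start_time.value
        + np.arange(n_epochs, dtype="int64") * int(cfg.epoch_seconds * 1e9)
    )
    wear = np.ones(n_epochs, dtype=bool)
    if nonwear is None:
        nonwear = detect_nonwear(rec, cfg)
    for start, end in nonwear:
        ends = times + pd.Timedelta(seconds=cfg.epoch_seconds)
        wear &= ~((times < end) & (ends > start))
    return EpochTensor(epochs, times, wear)


def save_epoch_tensor(tensor: EpochTensor, path) -> None:
    """Persist an EpochTensor as .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        epochs=tensor.epochs,
        epoch_start_ns=tensor.epoch_start_times.asi8,
        wear_mask=tensor.wear_mask,
    )
    meta = {
        "n_epochs": int(tensor.n_epochs),
        "shape": list(tensor.epochs.shape),
        "dtype": str(tensor.epochs.dtype),
        "times": "int64 ns since Unix epoch, UTC",
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_epoch_tensor(path) -> EpochTensor:
    with np.load(path) as z:
        return EpochTensor(
            z["epochs"], pd.DatetimeIndex(z["epoch_start_ns"]), z["wear_mask"]
        )
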
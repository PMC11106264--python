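"""Synthetic multi-night accelerometer cohorts with ground-truth hypnograms.

The generator emulates the structure of free-living wrist accelerometry that
the downstream pipeline relies on, without claiming physiological realism:

* a first-order Markov chain over the five AASM stages produces per-night
  hypnograms (geometric stage dwell times);
* the tri-axial signal is a slowly varying unit-norm gravity vector
  (piecewise constant between posture shifts) plus stage-dependent movement
  bursts and white device noise, so movement energy is ordered
  wake >> REM > N1 > N2 > N3;
* bursts have an abrupt attack and a gradual decay (asymmetric in time,
  like real wrist movements), which makes time-reversal discrimination a
  learnable self-supervision task;
* out-of-bed daytime signal is high-variance wake movement, so time in bed
  is detectable;
* diaries report true sleep onset/offset with uniform(-15, +15) min error.

All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EPOCH_SECONDS,
    STAGES,
    Hypnogram,
    RawRecording,
    write_hypnogram_csv,
    write_recording_csv,
)


class InvalidModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# models


@dataclass
class StageMarkovModel:
    """First-order Markov chain over AASM stages at 30-s epoch resolution."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    states: tuple = STAGES
    bedtime_mean_hour: float = 23.0  # clock hour
    bedtime_sd_minutes: float = 30.0  # night-to-night within a subject
    time_in_bed_mean_hours: float = 8.0
    time_in_bed_sd_minutes: float = 45.0  # night-to-night within a subject
    between_subject_bedtime_sd_minutes: float = 45.0
    between_subject_tib_sd_minutes: float = 40.0

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.validate()

    def validate(self) -> None:
        P, pi = self.transition_matrix, self.initial_distribution
        k = len(self.states)
        if P.shape != (k, k):
            raise InvalidModelError(f"transition matrix must be {k}x{k}")
        if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidModelError("transition matrix rows must be stochastic")
        if (pi < 0).any() or not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise InvalidModelError("initial distribution must be a probability vector")
        if self.time_in_bed_mean_hours <= 0:
            raise InvalidModelError("time_in_bed_mean_hours must be positive")

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution via the left eigenvector of eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        return v / v.sum()


@dataclass
class MovementModel:
    """Stage-dependent movement parameters (accelerations in mg).

    Per-stage dicts are keyed by stage label; ``daytime`` parameters govern
    the out-of-bed portion of a wear block.
    """

    baseline_noise_sd_mg: dict = field(
        default_factory=lambda: {"W": 40.0, "N1": 20.0, "N2": 16.0, "N3": 14.0, "R": 25.0}
    )
    baseline_lowpass_hz: float | None = 3.75  # band-limit of baseline movement
    burst_rate_per_min: dict = field(
        default_factory=lambda: {"W": 4.0, "N1": 0.8, "N2": 0.4, "N3": 0.1, "R": 1.5}
    )
    burst_amplitude_sd_mg: dict = field(
        default_factory=lambda: {"W": 150.0, "N1": 40.0, "N2": 30.0, "N3": 20.0, "R": 60.0}
    )
    burst_duration_s: float = 1.0
    burst_attack_fraction: float = 0.1  # attack much shorter than decay -> time-asymmetric
    orientation_drift_sd_deg: float = 20.0
    posture_shift_rate_per_hour: dict = field(
        default_factory=lambda: {"W": 12.0, "N1": 4.0, "N2": 2.0, "N3": 1.0, "R": 3.0}
    )
    daytime_activity_sd_mg: float = 100.0
    daytime_burst_rate_per_min: float = 8.0
    device_noise_sd_mg: float = 3.0

    def validate(self) -> None:
        for d in (self.baseline_noise_sd_mg, self.burst_rate_per_min, self.burst_amplitude_sd_mg):
            if any(v < 0 for v in d.values()):
                raise InvalidModelError("movement rates and sds must be non-negative")
        if self.device_noise_sd_mg < 0 or self.daytime_activity_sd_mg < 0:
            raise InvalidModelError("noise sds must be non-negative")


def default_stage_model(**overrides) -> StageMarkovModel:
    """Default overnight stage-transition preset.

    Sticky diagonals give plausible bout lengths (median N2 bout ~3.5 min);
    the chain starts awake (lights off) and passes through N1 into deeper
    sleep, with REM reachable from N2 and fragile to wake transitions.
    """
    P = np.array(
        [
            # W     N1    N2    N3    R
            [0.90, 0.08, 0.01, 0.00, 0.01],
            [0.04, 0.80, 0.15, 0.00, 0.01],
            [0.01, 0.02, 0.90, 0.05, 0.02],
            [0.00, 0.01, 0.06, 0.92, 0.01],
            [0.02, 0.02, 0.04, 0.00, 0.92],
        ]
    )
    pi = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    return StageMarkovModel(transition_matrix=P, initial_distribution=pi, **overrides)


def default_movement_model(**overrides) -> MovementModel:
    m = MovementModel()
    return replace(m, **overrides) if overrides else m


def burst_morphology_movement_model(**overrides) -> MovementModel:
    """Preset where stages differ by burst morphology, not baseline variance.

    All stages share the same baseline movement sd; wake and REM have many
    large bursts, deep NREM few small ones.  Per-epoch variance alone is a
    weak cue here, so classification must read movement shape — the regime
    where self-supervised pretraining of the convolutional extractor has
    something to contribute.
    """
    m = MovementModel(
        baseline_noise_sd_mg={s: 15.0 for s in STAGES},
        burst_rate_per_min={"W": 8.0, "N1": 2.0, "N2": 1.0, "N3": 0.3, "R": 4.0},
        burst_amplitude_sd_mg={"W": 120.0, "N1": 50.0, "N2": 40.0, "N3": 30.0, "R": 80.0},
        burst_attack_fraction=0.1,
    )
    return replace(m, **overrides) if overrides else m


# ---------------------------------------------------------------------------
# hypnogram simulation


def simulate_hypnogram(
    model: StageMarkovModel,
    n_epochs: int,
    seed: int,
    start_time="2024-01-01T23:00:00",
) -> Hypnogram:
    """Draw a stage sequence from the Markov chain.

    Identical seeds give identical sequences.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    k = len(model.states)
    cum_init = np.cumsum(model.initial_distribution)
    cum_trans = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(n_epochs)
    idx = np.empty(n_epochs, dtype=int)
    idx[0] = np.searchsorted(cum_init, u[0], side="right").clip(max=k - 1)
    for t in range(1, n_epochs):
        idx[t] = np.searchsorted(cum_trans[idx[t - 1]], u[t], side="right").clip(max=k - 1)
    labels = np.array(model.states, dtype=object)[idx]
    start = pd.Timestamp(start_time)
    times = pd.DatetimeIndex(
        [start + pd.Timedelta(seconds=EPOCH_SECONDS * i) for i in range(n_epochs)]
    )
    return Hypnogram(times, labels)


# ---------------------------------------------------------------------------
# signal simulation


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _gravity_track(
    n: int, rate: float, shift_rate_per_hour: np.ndarray, drift_sd_deg: float, rng
) -> np.ndarray:
    """Piecewise-constant unit gravity vector; new orientation at posture shifts.

    ``shift_rate_per_hour`` is per-sample (stage-dependent); events are drawn
    as per-sample Bernoulli with p = rate/3600/fs.
    """
    g = np.empty((n, 3))
    cur = _unit(rng.normal(size=3))
    p_shift = shift_rate_per_hour / 3600.0 / rate
    shifts = rng.random(n) < p_shift
    shifts[0] = False
    start = 0
    sigma = np.deg2rad(drift_sd_deg)
    for i in np.flatnonzero(shifts):
        g[start:i] = cur
        cur = _unit(cur + sigma * rng.normal(size=3))
        start = i
    g[start:] = cur
    return g


def _burst_envelope(n: int, attack_fraction: float) -> np.ndarray:
    """Abrupt-attack, gradual-decay envelope (time-asymmetric by design)."""
    na = max(1, int(round(n * attack_fraction)))
    nd = n - na
    env = np.empty(n)
    env[:na] = np.linspace(0.0, 1.0, na, endpoint=False) + 1.0 / na
    env[na:] = np.exp(-3.0 * np.arange(nd) / max(nd, 1))
    return env


def _movement_for_labels(
    labels: np.ndarray, movement: MovementModel, rate: float, rng
) -> np.ndarray:
    """Zero-mean movement signal (in g) for a per-epoch label sequence.

    Labels may include the pseudo-stage ``DAY`` for out-of-bed daytime wake.
    """
    spe = int(round(EPOCH_SECONDS * rate))  # samples per epoch
    n = len(labels) * spe
    sig = np.zeros((n, 3))

    def params(lab):
        if lab == "DAY":
            return (
                movement.daytime_activity_sd_mg,
                movement.daytime_burst_rate_per_min,
                movement.burst_amplitude_sd_mg["W"],
            )
        return (
            movement.baseline_noise_sd_mg[lab],
            movement.burst_rate_per_min[lab],
            movement.burst_amplitude_sd_mg[lab],
        )

    # baseline movement is band-limited (moving-average low-pass, variance
    # rescaled so the per-sample sd keeps its nominal value): wrist
    # acceleration is smooth at sub-second scale, unlike white device noise
    if movement.baseline_lowpass_hz:
        w = max(1, int(round(rate / movement.baseline_lowpass_hz)))
        kern = np.ones(w) / w
        scale = np.sqrt(w)
    else:
        w, kern, scale = 1, None, 1.0

    burst_len = max(2, int(round(movement.burst_duration_s * rate)))
    env = _burst_envelope(burst_len, movement.burst_attack_fraction)
    for e, lab in enumerate(labels):
        base_sd, burst_rate, burst_amp = params(lab)
        lo = e * spe
        if base_sd > 0:
            noise = rng.normal(scale=base_sd / 1000.0, size=(spe, 3))
            if w > 1:
                noise = np.apply_along_axis(
                    lambda v: np.convolve(v, kern, mode="same"), 0, noise
                ) * scale
            sig[lo : lo + spe] += noise
        n_bursts = rng.poisson(burst_rate * EPOCH_SECONDS / 60.0)
        for _ in range(n_bursts):
            s = lo + rng.integers(0, spe)
            ln = min(burst_len, n - s)
            amp = rng.normal(scale=burst_amp / 1000.0, size=3)
            sig[s : s + ln] += env[:ln, None] * amp[None, :]
    return sig


def _synthesize_block(
    labels: np.ndarray, movement: MovementModel, rate: float, rng
) -> np.ndarray:
    """Full signal for a label block: gravity + movement + device noise."""
    movement.validate()
    spe = int(round(EPOCH_SECONDS * rate))
    n = len(labels) * spe
    shift_rates = np.repeat(
        [
            movement.posture_shift_rate_per_hour.get(lab, movement.posture_shift_rate_per_hour["W"])
            for lab in labels
        ],
        spe,
    ).astype(float)
    sig = _gravity_track(n, rate, shift_rates, movement.orientation_drift_sd_deg, rng)
    sig = sig + _movement_for_labels(labels, movement, rate, rng)
    if movement.device_noise_sd_mg > 0:
        sig = sig + rng.normal(scale=movement.device_noise_sd_mg / 1000.0, size=(n, 3))
    return sig


def simulate_recording(
    hypnogram: Hypnogram,
    movement: MovementModel,
    sample_rate: float = 30.0,
    seed: int = 0,
    subject_id: str = "synthetic",
) -> RawRecording:
    """Tri-axial signal for a hypnogram: gravity + stage movement + noise.

    With all noise and burst parameters zero the signal is the pure gravity
    track, so every sample has Euclidean norm exactly 1 g.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    if sample_rate < 30:
        raise ValueError("sample_rate must be >= 30 Hz")
    rng = np.random.default_rng(seed)
    samples = _synthesize_block(hypnogram.labels, movement, sample_rate, rng)
    return RawRecording(
        subject_id=subject_id,
        start_time=hypnogram.epoch_start_times[0],
        sample_rate=sample_rate,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# subjects and cohorts


@dataclass
class SyntheticSubject:
    subject_id: str
    recordings: list  # RawRecording per continuous wear block
    hypnograms: list  # Hypnogram per night (in-bed epochs)
    diary: list  # (fell_asleep, woke_up) per night
    nonwear_truth: list  # (start, end) intervals
    strata: dict = field(default_factory=dict)


def _sub_seed(seed: int, *parts) -> int:
    h = hashlib.sha256(("/".join(map(str, parts)) + f":{seed}").encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def simulate_subject(
    subject_id: str,
    n_nights: int,
    stage_model: StageMarkovModel,
    movement: MovementModel,
    seed: int,
    first_night_date: str = "2024-03-04",
    margin_hours: float = 1.5,
    sample_rate: float = 30.0,
    nonwear_minutes: float = 0.0,
    strata: dict | None = None,
) -> SyntheticSubject:
    """One subject: per-night wear blocks spanning [bed-margin, rise+margin].

    Each night draws a bedtime ~ N(bedtime_mean, bedtime_sd) and a time in
    bed ~ N(mean, sd) (floored at 1 h), snapped to the 30-s grid.  Optional
    non-wear: one block of ``nonwear_minutes`` of pure stationarity inserted
    in the morning margin of the first night.
    """
    rng = np.random.default_rng(_sub_seed(seed, subject_id))
    base_date = pd.Timestamp(first_night_date)
    recordings, hypnograms, diary, nonwear_truth = [], [], [], []
    margin_epochs = int(round(margin_hours * 3600 / EPOCH_SECONDS))
    # stable subject traits: habitual bedtime and habitual time in bed
    bt_trait = rng.normal(0.0, stage_model.between_subject_bedtime_sd_minutes)
    tib_trait = rng.normal(0.0, stage_model.between_subject_tib_sd_minutes / 60)
    for night in range(n_nights):
        bt_minutes = rng.normal(
            stage_model.bedtime_mean_hour * 60 + bt_trait, stage_model.bedtime_sd_minutes
        )
        tib_h = max(
            1.0,
            rng.normal(
                stage_model.time_in_bed_mean_hours + tib_trait,
                stage_model.time_in_bed_sd_minutes / 60,
            ),
        )
        bed_start = base_date + pd.Timedelta(days=night, minutes=round(bt_minutes * 2) / 2)
        bed_start = bed_start.round("30s")
        n_epochs = max(2, int(round(tib_h * 3600 / EPOCH_SECONDS)))
        hyp = simulate_hypnogram(
            stage_model, n_epochs, _sub_seed(seed, subject_id, night, "hyp"), start_time=bed_start
        )
        hypnograms.append(hyp)

        block_labels = np.concatenate(
            [np.array(["DAY"] * margin_epochs, dtype=object), hyp.labels,
             np.array(["DAY"] * margin_epochs, dtype=object)]
        )
        block_start = bed_start - pd.Timedelta(seconds=margin_epochs * EPOCH_SECONDS)
        sig_rng = np.random.default_rng(_sub_seed(seed, subject_id, night, "sig"))
        samples = _synthesize_block(block_labels, movement, sample_rate, sig_rng)

        if nonwear_minutes > 0 and night == 0:
            # stationary insert in the trailing (morning) margin
            spe = int(round(EPOCH_SECONDS * sample_rate))
            nw_epochs = int(round(nonwear_minutes * 60 / EPOCH_SECONDS))
            nw_e0 = len(block_labels) - margin_epochs
            nw_epochs = min(nw_epochs, margin_epochs)
            g = _unit(sig_rng.normal(size=3))
            samples[nw_e0 * spe : (nw_e0 + nw_epochs) * spe] = g
            nw_start = block_start + pd.Timedelta(seconds=nw_e0 * EPOCH_SECONDS)
            nonwear_truth.append(
                (nw_start, nw_start + pd.Timedelta(seconds=nw_epochs * EPOCH_SECONDS))
            )

        recordings.append(
            RawRecording(subject_id, block_start, sample_rate, samples)
        )

        # sleep onset/offset truth from the hypnogram; diary adds +-15 min noise
        non_w = np.flatnonzero(hyp.labels != "W")
        onset = hyp.epoch_start_times[non_w[0]] if len(non_w) else bed_start
        offset = (
            hyp.epoch_start_times[non_w[-1]] + pd.Timedelta(seconds=EPOCH_SECONDS)
            if len(non_w)
            else hyp.end_time
        )
        d_rng = np.random.default_rng(_sub_seed(seed, subject_id, night, "diary"))
        fell = (onset + pd.Timedelta(minutes=d_rng.uniform(-15, 15))).round("s")
        woke = (offset + pd.Timedelta(minutes=d_rng.uniform(-15, 15))).round("s")
        fell = max(fell, block_start)
        woke = min(woke, block_start + pd.Timedelta(seconds=len(block_labels) * EPOCH_SECONDS))
        diary.append((fell, woke))
    return SyntheticSubject(
        subject_id, recordings, hypnograms, diary, nonwear_truth, strata or {}
    )


@dataclass
class CohortConfig:
    n_subjects: int = 6
    n_nights: int = 2
    seed: int = 0
    time_in_bed_mean_hours: float = 8.0
    time_in_bed_sd_minutes: float = 45.0
    bedtime_sd_minutes: float = 30.0
    margin_hours: float = 1.5
    sample_rate: float = 30.0
    nonwear_minutes: float = 0.0
    first_night_date: str = "2024-03-04"

    def stage_model(self) -> StageMarkovModel:
        return default_stage_model(
            time_in_bed_mean_hours=self.time_in_bed_mean_hours,
            time_in_bed_sd_minutes=self.time_in_bed_sd_minutes,
            bedtime_sd_minutes=self.bedtime_sd_minutes,
        )


def simulate_cohort(config: CohortConfig, out_dir) -> dict:
    """Write a cohort to disk; returns the manifest (also written as text).

    Layout: ``<out>/<subject>/recording_<k>.csv``, ``hypnogram_<k>.csv``,
    cohort-level ``diary.csv``, ``nonwear_truth.csv`` and ``manifest.txt``.
    Re-running with the same config reproduces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_model = config.stage_model()
    movement = default_movement_model()
    manifest = {"n_subjects": config.n_subjects, "n_nights": config.n_nights, "seed": config.seed}
    files, diary_rows, nonwear_rows = [], [], []
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        subj = simulate_subject(
            sid,
            config.n_nights,
            stage_model,
            movement,
            seed=config.seed,
            first_night_date=config.first_night_date,
            margin_hours=config.margin_hours,
            sample_rate=config.sample_rate,
            nonwear_minutes=config.nonwear_minutes,
        )
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        for k, (rec, hyp) in enumerate(zip(subj.recordings, subj.hypnograms)):
            rpath, hpath = sdir / f"recording_{k}.csv", sdir / f"hypnogram_{k}.csv"
            write_recording_csv(rec, rpath)
            write_hypnogram_csv(hyp, hpath)
            files += [str(rpath.relative_to(out)), str(hpath.relative_to(out))]
        for k, (fell, woke) in enumerate(subj.diary):
            diary_rows.append(
                {
                    "subject_id": sid,
                    "night_date": str((subj.hypnograms[k].epoch_start_times[0]).date()),
                    "fell_asleep": fell.isoformat(),
                    "woke_up": woke.isoformat(),
                }
            )
        for s, e in subj.nonwear_truth:
            nonwear_rows.append({"subject_id": sid, "start": s.isoformat(), "end": e.isoformat()})
    if config.n_subjects > 0:
        pd.DataFrame(diary_rows).to_csv(out / "diary.csv", index=False)
        files.append("diary.csv")
        if nonwear_rows:
            pd.DataFrame(nonwear_rows).to_csv(out / "nonwear_truth.csv", index=False)
            files.append("nonwear_truth.csv")
    manifest["files"] = files
    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            if k == "files":
                for f in v:
                    fh.write(f"file: {f}\n")
            else:
                fh.write(f"{k}: {v}\n")
    return manifest


# ---------------------------------------------------------------------------
# lightweight week-level truth for wear-time simulation


def simulate_week_sleep(
    subject_id: str,
    stage_model: StageMarkovModel,
    seed: int,
    n_days: int = 7,
    first_noon: str = "2024-03-04T12:00:00",
) -> pd.DataFrame:
    """Per-30-s-epoch sleep/wear truth over ``n_days`` noon-to-noon days.

    Returns a DataFrame with columns epoch_time, day (0-based noon-to-noon
    index), is_sleep, wear (all True; masking is applied downstream).  Raw
    signal is not generated: wear-time simulation needs only the epoch-level
    sleep indicator.
    """
    start = pd.Timestamp(first_noon)
    n_epochs = n_days * 24 * 3600 // EPOCH_SECONDS
    times = start + pd.to_timedelta(np.arange(n_epochs) * EPOCH_SECONDS, unit="s")
    is_sleep = np.zeros(n_epochs, dtype=bool)
    rng = np.random.default_rng(_sub_seed(seed, subject_id, "week"))
    bt_trait = rng.normal(0.0, stage_model.between_subject_bedtime_sd_minutes)
    tib_trait = rng.normal(0.0, stage_model.between_subject_tib_sd_minutes / 60)
    for day in range(n_days):
        bt_minutes = rng.normal(
            stage_model.bedtime_mean_hour * 60 + bt_trait, stage_model.bedtime_sd_minutes
        )
        tib_h = max(
            1.0,
            rng.normal(
                stage_model.time_in_bed_mean_hours + tib_trait,
                stage_model.time_in_bed_sd_minutes / 60,
            ),
        )
        n_bed = max(2, int(round(tib_h * 3600 / EPOCH_SECONDS)))
        bed_start = (
            start.normalize()
            + pd.Timedelta(days=day, minutes=round(bt_minutes * 2) / 2)
        ).round("30s")
        hyp = simulate_hypnogram(
            stage_model, n_bed, _sub_seed(seed, subject_id, "week", day), start_time=bed_start
        )
        i0 = int((hyp.epoch_start_times[0] - start).total_seconds() // EPOCH_SECONDS)
        sleep_idx = i0 + np.flatnonzero(hyp.labels != "W")
        sleep_idx = sleep_idx[(sleep_idx >= 0) & (sleep_idx < n_epochs)]
        is_sleep[sleep_idx] = True
    day_idx = (np.arange(n_epochs) * EPOCH_SECONDS) // (24 * 3600)
    return pd.DataFrame(
        {"epoch_time": times, "day": day_idx, "is_sleep": is_sleep, "wear": True}
    )
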
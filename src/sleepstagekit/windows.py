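"""Time-in-bed detection and the hand-crafted-feature baseline stager.

A random forest classifies each 30-s epoch as in-bed vs out-of-bed from
hand-crafted spatiotemporal features; a two-state hidden Markov model
smooths the per-epoch probabilities with Viterbi decoding; maximal in-bed
runs become candidate windows, windows within 60 min of one another are
merged, and the longest window per noon-to-noon interval is selected as the
overnight sleep opportunity.

The feature set is a standard actigraphy battery (movement intensity,
posture/arm angle, short-band frequency content and local context); exact
published feature lists vary by toolchain, so the set here is documented and
pluggable rather than canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .agreement import make_folds
from .core import EPOCH_SECONDS, EpochTensor, TimeInBedWindow

FEATURE_NAMES = (
    "enmo_mean_mg",
    "mean_x", "mean_y", "mean_z",
    "sd_x", "sd_y", "sd_z",
    "range_x", "range_y", "range_z",
    "vm_sd_mg",
    "arm_angle_mean_deg", "arm_angle_sd_deg",
    "arm_angle_change_deg",
    "power_ratio_03_3hz",
    "enmo_rolling_median_mg",
)


# ---------------------------------------------------------------------------
# features


def extract_features(tensor: EpochTensor, sample_rate: float = 30.0):
    """Per-epoch feature matrix for wear epochs.

    Returns ``(X, epoch_times)`` with one row per wear epoch, columns in
    FEATURE_NAMES order.  Arm angle is the elevation of the z axis above the
    horizontal plane, atan2(z, sqrt(x^2+y^2)), in degrees.  The power ratio
    is the fraction of non-DC vector-magnitude spectral power in the
    0.3-3 Hz band (voluntary-movement band).  The rolling ENMO median uses a
    centred 5-min (10-epoch) window over wear epochs.
    """
    wear = tensor.wear_mask
    x = tensor.epochs[wear].astype(float)  # (n, 3, spe)
    times = tensor.epoch_start_times[wear]
    n = x.shape[0]
    if n == 0:
        return np.empty((0, len(FEATURE_NAMES))), times
    norm = np.linalg.norm(x, axis=1)  # (n, spe)
    enmo = np.maximum(norm - 1.0, 0.0).mean(axis=1) * 1000.0
    mean = x.mean(axis=2)
    sd = x.std(axis=2, ddof=0)
    rng_ = x.max(axis=2) - x.min(axis=2)
    vm_sd = norm.std(axis=1, ddof=0) * 1000.0
    horiz = np.sqrt(x[:, 0] ** 2 + x[:, 1] ** 2)
    angle = np.degrees(np.arctan2(x[:, 2], horiz))  # (n, spe)
    ang_mean = angle.mean(axis=1)
    ang_sd = angle.std(axis=1, ddof=0)
    ang_change = np.abs(np.diff(ang_mean, prepend=ang_mean[0]))

    vm0 = norm - norm.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(vm0, axis=1)) ** 2
    freqs = np.fft.rfftfreq(norm.shape[1], d=1.0 / sample_rate)
    band = (freqs >= 0.3) & (freqs <= 3.0)
    total = spec[:, 1:].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, spec[:, band].sum(axis=1) / total, 0.0)

    enmo_med = (
        pd.Series(enmo).rolling(10, center=True, min_periods=1).median().to_numpy()
    )
    X = np.column_stack(
        [
            enmo,
            mean[:, 0], mean[:, 1], mean[:, 2],
            sd[:, 0], sd[:, 1], sd[:, 2],
            rng_[:, 0], rng_[:, 1], rng_[:, 2],
            vm_sd,
            ang_mean, ang_sd, ang_change,
            ratio,
            enmo_med,
        ]
    )
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    return X, times


# ---------------------------------------------------------------------------
# Viterbi

def viterbi(log_start: np.ndarray, log_trans: np.ndarray, log_lik: np.ndarray) -> np.ndarray:
    """Most probable state path. ``log_lik``: (T, S) per-step log-likelihoods.

    Ties are broken toward the lower state index (deterministic argmax).
    """
    T, S = log_lik.shape
    delta = log_start + log_lik[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(S)] + log_lik[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# window model


@dataclass
class SleepWindowModel:
    forest: RandomForestClassifier
    transition: np.ndarray  # (2, 2), state 1 = in-bed
    emission: np.ndarray  # (2, n_bins): P(prob-bin | state)
    start_prob: np.ndarray  # (2,)
    n_bins: int = 10
    merge_gap_minutes: float = 60.0

    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)[1:-1]


def fit_window_model(
    features: np.ndarray,
    in_bed: np.ndarray,
    seed: int = 0,
    n_estimators: int = 100,
    n_bins: int = 10,
) -> SleepWindowModel:
    """Train the epoch classifier and estimate the smoothing HMM.

    ``in_bed`` holds diary-derived booleans (epoch inside [fell_asleep,
    woke_up]).  The 2x2 transition matrix comes from the empirical label run
    lengths (p_stay = 1 - 1/mean run length); emissions are the forest's
    in-bed probability binned into ``n_bins`` equal-width bins, with Laplace
    smoothing.
    """
    y = np.asarray(in_bed, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("diary labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, min_samples_leaf=2, n_jobs=1
    )
    forest.fit(features, y.astype(int))

    trans = np.empty((2, 2))
    for s in (0, 1):
        runs = _run_lengths(y == bool(s))
        mean_run = np.mean(runs) if len(runs) else 1.0
        p_stay = min(max(1.0 - 1.0 / mean_run, 0.5), 0.999)
        trans[s] = [p_stay, 1 - p_stay] if s == 0 else [1 - p_stay, p_stay]

    p = forest.predict_proba(features)[:, 1]
    edges = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    bins = np.digitize(p, edges)
    emission = np.ones((2, n_bins))  # Laplace
    for s in (0, 1):
        cnt = np.bincount(bins[y == bool(s)], minlength=n_bins)
        emission[s] += cnt
    emission /= emission.sum(axis=1, keepdims=True)
    start = np.array([(~y).mean(), y.mean()])
    return SleepWindowModel(forest, trans, emission, start, n_bins)


def _run_lengths(mask: np.ndarray) -> list:
    out, count = [], 0
    for v in mask:
        if v:
            count += 1
        elif count:
            out.append(count)
            count = 0
    if count:
        out.append(count)
    return out


def predict_time_in_bed(
    model: SleepWindowModel, features: np.ndarray, epoch_times
) -> list:
    """Viterbi-decode forest probabilities into maximal in-bed windows."""
    if len(features) == 0:
        return []
    epoch_times = pd.DatetimeIndex(epoch_times)
    p = model.forest.predict_proba(features)[:, 1]
    bins = np.digitize(p, model.bin_edges())
    log_lik = np.log(model.emission[:, bins].T)  # (T, 2)
    path = viterbi(
        np.log(np.maximum(model.start_prob, 1e-12)),
        np.log(np.maximum(model.transition, 1e-12)),
        log_lik,
    )
    windows = []
    in_run = False
    for i, s in enumerate(path):
        if s == 1 and not in_run:
            start_i, in_run = i, True
        if in_run and (s == 0 or i == len(path) - 1):
            end_i = i if s == 0 else i + 1
            windows.append(
                TimeInBedWindow(
                    epoch_times[start_i],
                    epoch_times[end_i - 1] + pd.Timedelta(seconds=EPOCH_SECONDS),
                    source="detected",
                )
            )
            in_run = False
    return windows


def merge_windows(windows: list, gap_minutes: float = 60.0) -> list:
    """Merge consecutive windows separated by at most ``gap_minutes``.

    Applied transitively; overlapping inputs merge (gap <= 0).  Windows that
    absorbed another are labelled ``merged``.
    """
    if not windows:
        return []
    ws = sorted(windows, key=lambda w: (w.start, w.end))
    gap = pd.Timedelta(minutes=gap_minutes)
    out = [TimeInBedWindow(ws[0].start, ws[0].end, ws[0].source)]
    for w in ws[1:]:
        cur = out[-1]
        if w.start - cur.end <= gap:
            out[-1] = TimeInBedWindow(cur.start, max(cur.end, w.end), "merged")
        else:
            out.append(TimeInBedWindow(w.start, w.end, w.source))
    return out


def select_overnight_window(windows: list, day_boundary_hour: int = 12) -> dict:
    """Longest window per noon-to-noon interval.

    A window belongs to the interval containing its midpoint; the interval
    is keyed by the date of the noon that opens it.  Ties on length go to
    the earlier start.
    """
    by_day: dict = {}
    for w in windows:
        mid = w.midpoint
        key = mid.date() if mid.hour >= day_boundary_hour else (mid - pd.Timedelta(days=1)).date()
        best = by_day.get(key)
        if best is None:
            by_day[key] = w
            continue
        dur_w, dur_b = w.end - w.start, best.end - best.start
        if dur_w > dur_b or (dur_w == dur_b and w.start < best.start):
            by_day[key] = w
    return dict(sorted(by_day.items()))


# ---------------------------------------------------------------------------
# random-forest stage baseline


def rf_stage_baseline(
    features_by_subject: dict,
    labels_by_subject: dict,
    k: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> dict:
    """Subject-wise cross-validated 5-class RF predictions.

    ``features_by_subject``/``labels_by_subject`` map subject_id to the
    epoch feature matrix and AASM labels.  Returns subject_id -> predicted
    labels, for benchmarking against the deep stager with the same
    agreement battery.
    """
    folds = make_folds(list(features_by_subject), k=k, seed=seed)
    preds: dict = {}
    for i in range(k):
        test = folds.fold(i)
        train = [s for s in features_by_subject if s not in set(test)]
        Xtr = np.vstack([features_by_subject[s] for s in train])
        ytr = np.concatenate([np.asarray(labels_by_subject[s], dtype=object) for s in train])
        if len(set(ytr)) < 2:
            raise ValueError("training fold contains a single class")
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + i, min_samples_leaf=2, n_jobs=1
        )
        rf.fit(Xtr, ytr.astype(str))
        for s in test:
            preds[s] = rf.predict(features_by_subject[s]).astype(object)
    return preds
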
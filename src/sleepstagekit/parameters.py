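"""Hypnogram collapse, per-night sleep parameters and cohort filters.

Seven per-night sleep parameters are derived from the hypnogram restricted
to the time-in-bed window: total sleep duration (30 s x non-wake epochs),
sleep efficiency (total sleep / time in bed x 100), WASO (wake after the
first sleep-onset epoch), REM and NREM durations, and the REM/NREM ratios
as percentages of total sleep.  WASO counts all wake after sleep onset up
to the window end (no final-awakening truncation).  Overnight sleep
duration is the total sleep of the selected noon-to-noon window.

Cohort inclusion mirrors large-cohort practice: at least 3 calendar days
with >= 22 h of wear, at least one weekday and one weekend day among them,
and optional exclusion of shift workers and daylight-saving cross-overs
(supplied as metadata flags).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    EPOCH_SECONDS,
    STAGES,
    THREE_CLASS_MAP,
    TWO_CLASS_MAP,
    Hypnogram,
    TimeInBedWindow,
)


def collapse_hypnogram(hyp: Hypnogram, scheme: str) -> Hypnogram:
    """Collapse five-class labels: three_class (W/NREM/R) or two_class (W/SLEEP)."""
    maps = {"three_class": THREE_CLASS_MAP, "two_class": TWO_CLASS_MAP}
    if scheme not in maps:
        raise ValueError(f"unknown scheme {scheme!r}")
    mapping = maps[scheme]
    try:
        labels = np.array([mapping[l] for l in hyp.labels], dtype=object)
    except KeyError as exc:
        raise ValueError(f"unknown stage label {exc}") from None
    return Hypnogram(hyp.epoch_start_times, labels, hyp.epoch_seconds)


@dataclass
class NightSummary:
    total_sleep_duration_h: float
    sleep_efficiency_pct: float
    waso_min: float
    rem_duration_h: float
    nrem_duration_h: float
    rem_ratio_pct: float
    nrem_ratio_pct: float
    time_in_bed_h: float
    overnight_sleep_duration_h: float | None = None
    waso_defined: bool = True
    night_date: object = None
    subject_id: str = ""

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "night_date": self.night_date,
            "total_sleep_duration_h": self.total_sleep_duration_h,
            "sleep_efficiency_pct": self.sleep_efficiency_pct,
            "waso_min": self.waso_min,
            "rem_duration_h": self.rem_duration_h,
            "nrem_duration_h": self.nrem_duration_h,
            "rem_ratio_pct": self.rem_ratio_pct,
            "nrem_ratio_pct": self.nrem_ratio_pct,
            "time_in_bed_h": self.time_in_bed_h,
            "overnight_sleep_duration_h": self.overnight_sleep_duration_h,
        }


def summarize_night(hyp: Hypnogram, window: TimeInBedWindow) -> NightSummary:
    """Seven sleep parameters for the hypnogram epochs inside a bed window.

    Sleep = any non-wake label (works for the five-class alphabet and both
    collapsed schemes; REM duration is zero under the two-class scheme).
    An all-wake window yields efficiency 0 and WASO reported as 0 with
    ``waso_defined=False``.
    """
    starts = hyp.epoch_start_times
    ends = starts + pd.Timedelta(seconds=hyp.epoch_seconds)
    inside = (starts >= window.start) & (ends <= window.end)
    labels = hyp.labels[inside]
    if len(labels) == 0:
        raise ValueError("window contains no hypnogram epochs")
    eh = hyp.epoch_seconds / 3600.0
    is_sleep = labels != "W"
    total_sleep_h = float(is_sleep.sum() * eh)
    tib_h = window.duration_hours
    efficiency = 100.0 * total_sleep_h / tib_h if tib_h > 0 else 0.0
    rem_h = float((labels == "R").sum() * eh)
    nrem_h = total_sleep_h - rem_h
    if is_sleep.any():
        onset = int(np.flatnonzero(is_sleep)[0])
        waso_min = float((labels[onset:] == "W").sum() * hyp.epoch_seconds / 60.0)
        waso_defined = True
    else:
        waso_min, waso_defined = 0.0, False
    if total_sleep_h > 0:
        rem_ratio = 100.0 * rem_h / total_sleep_h
        nrem_ratio = 100.0 * nrem_h / total_sleep_h
    else:
        rem_ratio = nrem_ratio = 0.0
    return NightSummary(
        total_sleep_duration_h=total_sleep_h,
        sleep_efficiency_pct=min(efficiency, 100.0) if tib_h else 0.0,
        waso_min=waso_min,
        rem_duration_h=rem_h,
        nrem_duration_h=nrem_h,
        rem_ratio_pct=rem_ratio,
        nrem_ratio_pct=nrem_ratio,
        time_in_bed_h=tib_h,
        waso_defined=waso_defined,
        night_date=window.start.date(),
    )


def stage_probability_trajectory(
    hypnograms: list,
    clock_bin_minutes: int = 30,
    groups: list | None = None,
) -> pd.DataFrame:
    """Mean stage probability per clock-time bin (optionally per group).

    For each bin of the 24-h clock, the probability of a stage is the
    fraction of person-epochs in that stage among all possible person-epochs
    (n_hypnograms x epochs per bin); epochs not covered by a hypnogram count
    as ``out_of_window``, so per-bin probabilities over
    {W, N1, N2, N3, R, out_of_window} sum to 1.
    """
    if not hypnograms:
        raise ValueError("need at least one hypnogram")
    if (24 * 60) % clock_bin_minutes != 0:
        raise ValueError("bins must divide 24 h evenly")
    n_bins = 24 * 60 // clock_bin_minutes
    epochs_per_bin = clock_bin_minutes * 60 // EPOCH_SECONDS
    if groups is None:
        groups = ["all"] * len(hypnograms)
    out_rows = []
    stage_list = list(STAGES) + ["out_of_window"]
    for grp in sorted(set(groups)):
        hyps = [h for h, g in zip(hypnograms, groups) if g == grp]
        counts = np.zeros((n_bins, len(STAGES)))
        for hyp in hyps:
            secs = (
                hyp.epoch_start_times.hour * 3600
                + hyp.epoch_start_times.minute * 60
                + hyp.epoch_start_times.second
            )
            bins = np.asarray(secs) // (clock_bin_minutes * 60)
            for si, stage in enumerate(STAGES):
                np.add.at(counts[:, si], bins[hyp.labels == stage], 1)
        denom = len(hyps) * epochs_per_bin
        probs = counts / denom
        oow = 1.0 - probs.sum(axis=1)
        full = np.column_stack([probs, oow])
        for b in range(n_bins):
            for si, stage in enumerate(stage_list):
                out_rows.append(
                    {
                        "group": grp,
                        "bin_start_minutes": b * clock_bin_minutes,
                        "stage": stage,
                        "probability": full[b, si],
                    }
                )
    return pd.DataFrame(out_rows)


@dataclass
class CohortFilterConfig:
    min_wear_hours_per_day: float = 22.0
    min_valid_days: int = 3
    require_weekday_and_weekend: bool = True
    exclude_shift_workers: bool = True
    exclude_dst_crossover: bool = True

    def __post_init__(self):
        if self.min_wear_hours_per_day <= 0 or self.min_valid_days <= 0:
            raise ValueError("thresholds must be positive")


def filter_cohort(
    per_day_wear: pd.DataFrame,
    cfg: CohortFilterConfig | None = None,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inclusion decision per subject with enumerated exclusion reasons.

    ``per_day_wear`` columns: subject_id, date, wear_hours.  A valid day has
    wear >= ``min_wear_hours_per_day``; inclusion needs >= ``min_valid_days``
    valid days and, if required, at least one valid weekday and one valid
    weekend (Sat/Sun) day.  ``metadata`` (optional) columns: subject_id,
    shift_worker, dst_crossover (booleans).
    """
    cfg = cfg or CohortFilterConfig()
    meta = {}
    if metadata is not None:
        meta = metadata.set_index("subject_id").to_dict("index")
    rows = []
    for sid, grp in per_day_wear.groupby("subject_id"):
        reasons = []
        dates = pd.to_datetime(grp["date"])
        valid = grp["wear_hours"].to_numpy() >= cfg.min_wear_hours_per_day
        n_valid = int(valid.sum())
        if n_valid < cfg.min_valid_days:
            reasons.append("insufficient valid days")
        if cfg.require_weekday_and_weekend:
            dow = dates.dt.dayofweek.to_numpy()
            has_weekday = bool((valid & (dow < 5)).any())
            has_weekend = bool((valid & (dow >= 5)).any())
            if not (has_weekday and has_weekend):
                reasons.append("missing weekday or weekend day")
        m = meta.get(sid, {})
        if cfg.exclude_shift_workers and m.get("shift_worker", False):
            reasons.append("shift worker")
        if cfg.exclude_dst_crossover and m.get("dst_crossover", False):
            reasons.append("daylight saving cross-over")
        rows.append(
            {
                "subject_id": sid,
                "included": not reasons,
                "n_valid_days": n_valid,
                "reasons": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")
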
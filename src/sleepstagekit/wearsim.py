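"""Minimum-wear-time simulation via intraclass correlation.

To find how much device wear is needed for stable weekly sleep estimates,
random missing data is imposed on subjects with complete 7-day wear: for a
masking scheme (hours retained per day, days retained), contiguous blocks
are removed until each retained day keeps exactly the target wear and only
the chosen days remain.  The weekly average sleep duration from masked data
is compared with the complete-data value through the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1), computed
from explicit ANOVA sums of squares.  A grid search over (hours, days)
reports the cheapest scheme whose average ICC exceeds a threshold
(0.75 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EPOCH_SECONDS

EPOCHS_PER_DAY = 24 * 3600 // EPOCH_SECONDS
EPOCHS_PER_HOUR = 3600 // EPOCH_SECONDS


@dataclass
class MaskingScheme:
    hours_retained_per_day: float
    days_retained: int
    block_minutes: float = 60.0  # removed-block granularity

    def __post_init__(self):
        if not 0 < self.hours_retained_per_day <= 24:
            raise ValueError("hours_retained_per_day must be in (0, 24]")
        if not 1 <= self.days_retained <= 7:
            raise ValueError("days_retained must be in 1..7")


@dataclass
class ICCResult:
    icc: float
    n_subjects: int
    between_subject_var: float
    error_var: float
    defined: bool = True


def apply_wear_mask(week: pd.DataFrame, scheme: MaskingScheme, rng) -> pd.DataFrame:
    """Mask a complete 7-day week (from ``synthetic.simulate_week_sleep``).

    Keeps ``days_retained`` randomly chosen days; within each kept day,
    removes uniformly placed non-overlapping contiguous blocks (default 1 h
    each) until exactly ``hours_retained_per_day`` of wear remain.  The
    full-data scheme (24 h x 7 d) removes nothing.  Deterministic under a
    seeded generator.
    """
    if not week["wear"].all():
        raise ValueError("apply_wear_mask expects a complete (all-wear) week")
    out = week.copy()
    wear = out["wear"].to_numpy().copy()
    days = np.sort(rng.choice(7, size=scheme.days_retained, replace=False))
    day_idx = out["day"].to_numpy()
    wear[~np.isin(day_idx, days)] = False
    remove_h = 24.0 - scheme.hours_retained_per_day
    if remove_h > 0:
        n_remove = int(round(remove_h * EPOCHS_PER_HOUR))
        block = max(1, int(round(scheme.block_minutes * 60 / EPOCH_SECONDS)))
        for d in days:
            pos = np.flatnonzero(day_idx == d)
            removed = 0
            guard = 0
            while removed < n_remove and guard < 10000:
                guard += 1
                ln = min(block, n_remove - removed)
                s = int(rng.integers(0, len(pos) - ln + 1))
                seg = pos[s : s + ln]
                if wear[seg].all():
                    wear[seg] = False
                    removed += ln
            if removed < n_remove:  # fall back: remove from remaining wear
                rest = pos[wear[pos]]
                wear[rest[: n_remove - removed]] = False
    out["wear"] = wear
    return out


def weekly_sleep_estimate(week: pd.DataFrame) -> float:
    """Weekly average sleep duration (h/day) over days with any retained wear.

    Per noon-to-noon day: 30 s x sleep epochs observed during wear; the
    weekly value is the mean over retained days.  NaN when no day retains
    wear.
    """
    wear = week["wear"].to_numpy()
    day = week["day"].to_numpy()
    sleep = week["is_sleep"].to_numpy() & wear
    vals = []
    for d in np.unique(day):
        sel = day == d
        if wear[sel].any():
            vals.append(sleep[sel].sum() * EPOCH_SECONDS / 3600.0)
    return float(np.mean(vals)) if vals else float("nan")


def icc_two_way(pairs: np.ndarray) -> ICCResult:
    """ICC(2,1) from a two-way ANOVA decomposition of an (n, k) table.

    Rows are subjects, columns measurements (here k=2: masked and full).
    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    Degenerate (zero total variance) input is flagged as undefined.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2, k >= 2) table")
    n, k = x.shape
    grand = x.mean()
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_mean - grand) ** 2).sum()
    ss_cols = n * ((col_mean - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(ss_total, 0.0):
        return ICCResult(float("nan"), n, 0.0, 0.0, defined=False)
    icc = (msr - mse) / denom
    return ICCResult(
        icc=float(icc),
        n_subjects=n,
        between_subject_var=float(max((msr - mse) / k, 0.0)),
        error_var=float(mse),
    )


def wear_grid_search(
    weeks: list,
    hours_grid=None,
    days_grid=None,
    icc_threshold: float = 0.75,
    reps: int = 5,
    seed: int = 0,
) -> tuple:
    """Average ICC between masked and complete weekly estimates per grid cell.

    ``weeks``: complete 7-day weeks (one per subject).  Returns
    ``(minimal_scheme | None, grid DataFrame)``; the minimal scheme is the
    cell with the least total retained hours (hours x days; ties broken by
    fewer hours then fewer days) among cells with mean ICC > threshold.
    The grid table also flags violations of the expected monotonicity of
    ICC in retained hours.
    """
    hours_grid = list(hours_grid if hours_grid is not None else (16, 18, 20, 22, 24))
    days_grid = list(days_grid if days_grid is not None else (1, 3, 5, 7))
    full = np.array([weekly_sleep_estimate(w) for w in weeks])
    rows = []
    rng = np.random.default_rng(seed)
    for h in hours_grid:
        for d in days_grid:
            scheme = MaskingScheme(h, d)
            iccs = []
            for _ in range(reps):
                masked = np.array(
                    [weekly_sleep_estimate(apply_wear_mask(w, scheme, rng)) for w in weeks]
                )
                ok = np.isfinite(masked)
                res = icc_two_way(np.column_stack([masked[ok], full[ok]]))
                iccs.append(res.icc)
            rows.append(
                {
                    "hours": h,
                    "days": d,
                    "mean_icc": float(np.mean(iccs)),
                    "sd_icc": float(np.std(iccs, ddof=1)) if reps > 1 else 0.0,
                    "n_reps": reps,
                }
            )
    grid = pd.DataFrame(rows)
    grid["monotonicity_violation"] = False
    for d in days_grid:
        sub = grid[grid["days"] == d].sort_values("hours")
        viol = sub["mean_icc"].diff().fillna(0.0) < -0.02  # tolerate MC noise
        grid.loc[sub.index, "monotonicity_violation"] = viol.to_numpy()
    passing = grid[grid["mean_icc"] > icc_threshold]
    if passing.empty:
        return None, grid
    best = passing.assign(total=passing["hours"] * passing["days"]).sort_values(
        ["total", "hours", "days"]
    )
    row = best.iloc[0]
    return MaskingScheme(float(row["hours"]), int(row["days"])), grid
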
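"""From verified detections to behavioural records and group comparisons.

* :func:`hourly_proportions` aggregates detection events into grunt
  seconds per clock hour (events spanning an hour boundary are split).
* :func:`peak_rut_date` backdates the mean calving date by the 221-day
  gestation length to estimate the peak of the rut.
* :func:`status_contrast_test` is a Wilcoxon rank-sum (Mann-Whitney)
  comparison of dominant versus subdominant hourly proportions, exact by
  enumeration for small samples and normal-approximate with tie
  correction otherwise.

The model fit itself lives in :mod:`rutvox.hgam` and is re-exported here.
"""

from __future__ import annotations

import datetime as dt
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .detector import DetectionEvent
from .hgam import HGAMFit, HGAMSpec, diagnostics, fit_hgam, predict_smooths  # noqa: F401

__all__ = [
    "hourly_proportions",
    "peak_rut_date",
    "status_contrast_test",
    "rank_sum_test",
    "fit_hgam",
    "predict_smooths",
    "diagnostics",
    "HGAMSpec",
    "HGAMFit",
]


def hourly_proportions(
    events: list[DetectionEvent],
    file_start_clock: dt.datetime,
    file_duration_s: float,
    individual: str,
    status_log: list[tuple] | None = None,
    peak_date: dt.date | None = None,
) -> pd.DataFrame:
    """Aggregate detection events into per-clock-hour grunt proportions.

    Each event contributes its duration in seconds to every clock hour it
    overlaps (events spanning a boundary are split).  The proportion is
    grunt seconds / 3600.  Only hours touched by the recording appear
    (recorded hours without grunts get proportion 0; unrecorded hours are
    omitted, not zero-filled).  `status_log` is a list of
    ``(start_datetime, end_datetime, status)`` intervals; hours outside it
    are labelled "unknown".
    """
    for e1, e2 in zip(events, events[1:]):
        if e2.start_s < e1.end_s:
            raise ValueError(
                f"events overlap or are unsorted: [{e1.start_s}, {e1.end_s}) "
                f"then [{e2.start_s}, {e2.end_s})"
            )
    seconds: dict[dt.datetime, float] = {}
    first_hour = file_start_clock.replace(minute=0, second=0, microsecond=0)
    end_clock = file_start_clock + dt.timedelta(seconds=file_duration_s)
    h = first_hour
    while h < end_clock:
        seconds[h] = 0.0
        h += dt.timedelta(hours=1)

    for e in events:
        t0 = file_start_clock + dt.timedelta(seconds=e.start_s)
        t1 = file_start_clock + dt.timedelta(seconds=e.end_s)
        cur = t0
        while cur < t1:
            hour_start = cur.replace(minute=0, second=0, microsecond=0)
            hour_end = hour_start + dt.timedelta(hours=1)
            chunk_end = min(t1, hour_end)
            seconds[hour_start] = seconds.get(hour_start, 0.0) + (chunk_end - cur).total_seconds()
            cur = chunk_end

    def status_at(t: dt.datetime) -> str:
        if status_log:
            for s0, s1, st in status_log:
                if s0 <= t < s1:
                    return st
        return "unknown"

    rows = []
    for hour_start in sorted(seconds):
        row = {
            "individual": individual,
            "date": hour_start.date(),
            "hour": hour_start.hour,
            "status": status_at(hour_start),
            "proportion": seconds[hour_start] / 3600.0,
        }
        if peak_date is not None:
            row["day_rel_peak"] = (hour_start.date() - peak_date).days
        rows.append(row)
    return pd.DataFrame(rows)


def peak_rut_date(calving_dates, gestation_days: int = 221) -> dt.date:
    """Backdate the mean calving date by the gestation length.

    The mean calendar date is the average of day offsets from the earliest
    date, rounded to the nearest day (half rounds up).
    """
    dates = list(calving_dates)
    if not dates:
        raise ValueError("at least one calving date is required")
    base = min(dates)
    offsets = [(d - base).days for d in dates]
    mean_off = int(np.floor(np.mean(offsets) + 0.5))
    return base + dt.timedelta(days=mean_off) - dt.timedelta(days=int(gestation_days))


def rank_sum_test(x, y, exact_limit: int = 20) -> dict:
    """Wilcoxon rank-sum test of two samples.

    The statistic is the Mann-Whitney U of the first sample reported as W
    (rank sum of group 1 minus n1(n1+1)/2, R's convention).  The two-sided
    p-value is exact — full enumeration of group assignments — when
    n1+n2 <= `exact_limit`, and a tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        obs_dev = abs(W - mean_u)
        count = 0
        total = 0
        base = (n1 * (n1 + 1)) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - base
            if abs(u - mean_u) >= obs_dev - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        n = n1 + n2
        _vals, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        if sigma == 0:
            p = 1.0
        else:
            z = (W - mean_u - np.sign(W - mean_u) * 0.5) / sigma  # continuity correction
            p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return {
        "W": W,
        "p": min(p, 1.0),
        "method": method,
        "mean_x": float(x.mean()),
        "mean_y": float(y.mean()),
        "n_x": int(n1),
        "n_y": int(n2),
    }


def status_contrast_test(records: pd.DataFrame) -> dict:
    """Rank-sum comparison of dominant vs subdominant hourly proportions."""
    dom = records.loc[records["status"] == "dominant", "proportion"].to_numpy()
    sub = records.loc[records["status"] == "subdominant", "proportion"].to_numpy()
    out = rank_sum_test(dom, sub)
    out["mean_dominant"] = out.pop("mean_x")
    out["mean_subdominant"] = out.pop("mean_y")
    return out
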
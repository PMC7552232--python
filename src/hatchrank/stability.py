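"""Weekly intervals and the modified stability index S.

S quantifies how much the day-to-day rank order moves inside a time
interval, on a 0 (maximally unstable) to 1 (no rank changes) scale.  For
each consecutive pair of days in the interval:

* dense ranks (1 = highest Elo score) are computed on both days;
* each individual contributes its absolute rank change, weighted by its
  Elo score on the earlier day standardized to [0, 1] within that day
  (min-max), so changes near the top of the hierarchy weigh more than
  churn at the bottom;
* the maximal attainable weighted change for that day pair is the one a
  complete top-to-bottom reversal would produce under the same weights,
  sum_i w_i * |n_ranks + 1 − 2 r_i|.

S = 1 − (observed weighted sum over the interval) / (maximal weighted sum),
so a change-free interval scores exactly 1 and a complete reversal on every
day scores 0.  Scores on days without interactions are the carried-forward
step function of the sequential Elo trajectory, so rank changes can only
occur across interaction days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._core import dense_rank_desc
from .errors import ValidationError

__all__ = ["make_weekly_intervals", "stability_index", "stability_series"]


def make_weekly_intervals(span_start, span_end, n_intervals: int = 30):
    """Split [span_start, span_end) into ``n_intervals`` contiguous
    half-open 7-day intervals, the last one extended or truncated to end
    exactly at ``span_end``."""
    start = pd.Timestamp(span_start)
    end = pd.Timestamp(span_end)
    if n_intervals < 1:
        raise ValidationError("n_intervals must be >= 1")
    last_start = start + pd.Timedelta(days=7 * (n_intervals - 1))
    if end <= last_start:
        raise ValidationError(
            f"span [{start.date()}, {end.date()}) too short for "
            f"{n_intervals} weekly intervals"
        )
    intervals = []
    for i in range(n_intervals):
        lo = start + pd.Timedelta(days=7 * i)
        hi = start + pd.Timedelta(days=7 * (i + 1)) if i < n_intervals - 1 else end
        intervals.append((lo, hi))
    return intervals


def _daily_scores(trajectory) -> pd.DataFrame:
    if isinstance(trajectory, pd.DataFrame):
        return trajectory
    daily = getattr(trajectory, "daily_scores_", None)
    if daily is None:
        raise ValidationError(
            "expected a fitted EloRating or a date-by-individual score frame"
        )
    return daily


def _standardized_weights(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.ones_like(scores)
    return (scores - lo) / (hi - lo)


def stability_index(trajectory, interval) -> tuple[float, int]:
    """Modified stability index S and the raw rank-change count for one
    half-open interval.  Requires at least two days with defined scores."""
    daily = _daily_scores(trajectory)
    lo, hi = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
    window = daily.loc[(daily.index >= lo) & (daily.index < hi)]
    if len(window) < 2:
        raise ValidationError(
            f"interval [{lo.date()}, {hi.date()}) has fewer than 2 days of scores"
        )
    values = window.to_numpy(dtype=float)
    observed = 0.0
    maximal = 0.0
    n_changes = 0
    for t in range(len(values) - 1):
        r0 = dense_rank_desc(values[t])
        r1 = dense_rank_desc(values[t + 1])
        w = _standardized_weights(values[t])
        change = np.abs(r1 - r0)
        observed += float(np.sum(w * change))
        n_ranks = int(r0.max())
        maximal += float(np.sum(w * np.abs(n_ranks + 1 - 2 * r0)))
        n_changes += int(np.count_nonzero(change))
    if maximal == 0.0:
        return 1.0, n_changes
    s = 1.0 - observed / maximal
    return float(min(max(s, 0.0), 1.0)), n_changes


def stability_series(trajectory, intervals, group_id=None) -> pd.DataFrame:
    """S per interval as a tidy frame: interval bounds, S, change count.

    Intervals that do not contain at least two days of the trajectory are
    reported with S = NaN rather than raising, so a study span slightly
    shorter than the interval grid still yields a series.
    """
    rows = []
    for lo, hi in intervals:
        try:
            s, n = stability_index(trajectory, (lo, hi))
        except ValidationError:
            s, n = np.nan, 0
        rows.append(
            {
                "group": group_id,
                "interval_start": pd.Timestamp(lo),
                "interval_end": pd.Timestamp(hi),
                "S": s,
                "n_changes": n,
            }
        )
    return pd.DataFrame(rows)
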
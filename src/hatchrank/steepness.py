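"""Hierarchy steepness: P(higher-ranked contestant wins) vs rank difference.

A flat hierarchy gives probabilities near 0.5 at every rank difference; a
steep one rises quickly with the difference.  The curve is estimated over
cumulative periods (study start to +1 month, +2 months, ... whole span) so
its temporal evolution tracks how decisively the hierarchy settles.

Ranks are the dense ranks of the contestants' Elo scores immediately
*before* each event (so earlier same-day interactions count), taken from
the event log of a fitted :class:`~hatchrank.elo.EloRating`.  Events where
the two contestants are tied in rank carry no direction and are excluded
from the curve but counted separately.

The fitted curve is a two-parameter logistic, P(win | d) =
1/(1+exp(−(a + b·d))), estimated by maximum likelihood on the event-level
binary outcomes with box bounds |a|,|b| ≤ 30 so that perfectly decided
data (all higher-ranked wins) degrade gracefully to a saturated curve
instead of a separation failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import ValidationError

__all__ = ["make_cumulative_periods", "winner_prob_curve", "SteepnessCurve", "fit_logistic_curve"]

_PARAM_BOUND = 30.0


def make_cumulative_periods(span_start, span_end, n_periods: int = 7):
    """Nested half-open periods growing by one calendar month at a time.

    Period i (1-based) is [span_start, span_start + i months) for
    i < n_periods; the last period runs to the end of the span inclusive
    ([span_start, span_end + 1 day) in half-open terms).
    """
    start = pd.Timestamp(span_start)
    end = pd.Timestamp(span_end)
    if n_periods < 1:
        raise ValidationError("n_periods must be >= 1")
    if start + pd.DateOffset(months=n_periods - 1) >= end + pd.Timedelta(days=1):
        raise ValidationError(
            f"span [{start.date()}, {end.date()}] too short for {n_periods} "
            "monthly periods"
        )
    periods = []
    for i in range(1, n_periods):
        periods.append((start, start + pd.DateOffset(months=i)))
    periods.append((start, end + pd.Timedelta(days=1)))
    return periods


@dataclass
class SteepnessCurve:
    """Win-probability-vs-rank-difference curve for one cumulative period."""

    period: tuple
    points: pd.DataFrame = field(repr=False)  # rank_diff, n, wins_higher, prop
    fit_intercept: float = np.nan
    fit_slope: float = np.nan
    n_events: int = 0
    n_tied: int = 0
    converged: bool = False
    saturated: bool = False

    def predict(self, rank_diff):
        return expit(self.fit_intercept + self.fit_slope * np.asarray(rank_diff, float))


def fit_logistic_curve(d: np.ndarray, y: np.ndarray):
    """Two-parameter logistic MLE of P(y=1 | d); returns
    (intercept, slope, converged, saturated)."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)

    def nll(theta):
        eta = theta[0] + theta[1] * d
        # log(1+exp) written stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    def grad(theta):
        p = expit(theta[0] + theta[1] * d)
        r = p - y
        return np.array([r.sum(), (r * d).sum()])

    res = minimize(
        nll,
        x0=np.zeros(2),
        jac=grad,
        method="L-BFGS-B",
        bounds=[(-_PARAM_BOUND, _PARAM_BOUND)] * 2,
    )
    saturated = bool(np.any(np.abs(res.x) >= _PARAM_BOUND - 1e-6))
    return float(res.x[0]), float(res.x[1]), bool(res.success), saturated


def winner_prob_curve(trajectory, period) -> SteepnessCurve:
    """Estimate the steepness curve for one period of a fitted trajectory.

    ``trajectory`` is a fitted :class:`~hatchrank.elo.EloRating` (typically
    at the best constant k); ``period`` a half-open (start, end) pair.
    """
    events = getattr(trajectory, "events_", None)
    if events is None:
        raise ValidationError("winner_prob_curve needs a fitted EloRating")
    lo, hi = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    sel = events[(events["date"] >= lo) & (events["date"] < hi)]
    rank_w = sel["rank_winner"].to_numpy()
    rank_l = sel["rank_loser"].to_numpy()
    tied = rank_w == rank_l
    n_tied = int(tied.sum())
    sel = sel[~tied]
    if len(sel) == 0:
        raise ValidationError(
            f"period [{lo.date()}, {hi.date()}) has no rank-unequal events"
        )
    rank_w, rank_l = rank_w[~tied], rank_l[~tied]
    d = np.abs(rank_w - rank_l)
    higher_won = (rank_w < rank_l).astype(int)  # rank 1 = highest

    pts = (
        pd.DataFrame({"rank_diff": d, "win": higher_won})
        .groupby("rank_diff")
        .agg(n=("win", "size"), wins_higher=("win", "sum"))
        .reset_index()
    )
    pts["prop"] = pts["wins_higher"] / pts["n"]
    a, b, ok, saturated = fit_logistic_curve(d, higher_won)
    return SteepnessCurve(
        period=(lo, hi),
        points=pts,
        fit_intercept=a,
        fit_slope=b,
        n_events=int(len(sel)),
        n_tied=n_tied,
        converged=ok,
        saturated=saturated,
    )


def steepness_table(trajectory, periods, group_id=None) -> pd.DataFrame:
    """Tidy per-period curve points plus fit parameters for export."""
    rows = []
    for period in periods:
        try:
            curve = winner_prob_curve(trajectory, period)
        except ValidationError:
            continue
        for _, p in curve.points.iterrows():
            rows.append(
                {
                    "group": group_id,
                    "period_end": curve.period[1],
                    "rank_diff": int(p["rank_diff"]),
                    "n": int(p["n"]),
                    "wins_higher": int(p["wins_higher"]),
                    "prop": float(p["prop"]),
                    "fit_intercept": curve.fit_intercept,
                    "fit_slope": curve.fit_slope,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "period_end",
            "rank_diff",
            "n",
            "wins_higher",
            "prop",
            "fit_intercept",
            "fit_slope",
        ],
    )
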
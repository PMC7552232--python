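"""Sequential Elo rating of a chronological dyadic-interaction sequence.

The central object is :class:`EloRating`, a scikit-learn style estimator.
``fit`` folds the Elo update over a validated single-group chronology and
exposes the full rating trajectory:

``events_``
    one row per interaction with the pre/post scores of both contestants,
    the expected win probability of the realized winner, the score transfer
    ``delta`` and the contestants' dense ranks immediately before the event;

``daily_scores_``
    a calendar-day by individual matrix of end-of-day scores, carrying the
    last value forward over non-observation days (a step function);

``log_likelihood_``
    the winner-sequence log-likelihood sum(ln P(realized winner)), the
    objective later used to fit k and start values.

Every event is zero-sum: the winner gains ``k * (1 − p_expected)`` and the
loser loses the same amount, so with equal starting scores the group total
is conserved exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._core import (
    BEHAVIORS,
    behavior_codes,
    dense_rank_desc,
    k_vector,
    win_probability,
)
from .errors import ConfigurationError, ValidationError

__all__ = [
    "EloRating",
    "expected_win_probability",
    "update_ratings",
    "compute_trajectory",
    "daily_ranks",
]


def expected_win_probability(score_a, score_b, dialect: str = "normal"):
    """P(a beats b) given current scores, under the chosen dialect.

    ``normal``:  Phi((a−b) / (200·sqrt(2)));  ``logistic``: 1/(1+10^(−(a−b)/400)).
    Strictly increasing in (a − b); exactly 0.5 at equality in both dialects.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("scores must be finite")
    return win_probability(np.asarray(score_a, float) - np.asarray(score_b, float), dialect)


def update_ratings(state: dict, winner, loser, behavior: str, k, dialect: str = "normal") -> dict:
    """One Elo update on a dict of current scores; returns a new dict.

    ``k`` is a positive scalar or a mapping over HB/M/TB.  The winner gains
    ``k·(1 − p_exp)`` and the loser loses the same amount (zero-sum); all
    other scores are unchanged.
    """
    if winner not in state or loser not in state:
        raise ConfigurationError("both contestants need a current score")
    if behavior not in BEHAVIORS:
        raise ConfigurationError(f"unknown behavior {behavior!r}")
    kvec = k_vector(k)
    kb = kvec[BEHAVIORS.index(behavior)]
    p = win_probability(state[winner] - state[loser], dialect)
    delta = kb * (1.0 - p)
    out = dict(state)
    out[winner] += delta
    out[loser] -= delta
    return out


class EloRating(BaseEstimator):
    """Sequential Elo-rating trajectory for one group of individuals.

    Parameters
    ----------
    k : float or mapping {HB, M, TB} -> float, default 100
        Update constant(s); the maximal per-event score change.  A mapping
        gives the behavior-dependent ("three-interaction") model.
    start_score : float, default 1000
        Score assigned to every individual at the start.
    start_scores : mapping individual -> float, optional
        Per-individual starting scores; must cover every individual in the
        fitted records.  Overrides ``start_score``.
    dialect : {"normal", "logistic"}, default "normal"
        Expectation function mapping rating difference to win probability.
    """

    def __init__(self, k=100.0, start_score=1000.0, start_scores=None, dialect="normal"):
        self.k = k
        self.start_score = start_score
        self.start_scores = start_scores
        self.dialect = dialect

    # ------------------------------------------------------------------
    def _start_vector(self, individuals) -> np.ndarray:
        if self.start_scores is None:
            return np.full(len(individuals), float(self.start_score))
        missing = [i for i in individuals if i not in self.start_scores]
        if missing:
            raise ConfigurationError(
                f"start_scores missing individuals {missing!r}"
            )
        return np.array([float(self.start_scores[i]) for i in individuals])

    def fit(self, interactions: pd.DataFrame, y=None):
        """Fold the Elo update over a validated single-group chronology."""
        df = interactions
        required = {"date", "winner", "loser", "behavior"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"interactions frame needs columns {sorted(required)}"
            )
        if "group" in df.columns and df["group"].nunique() > 1:
            raise ValidationError("EloRating.fit expects a single group")
        if "seq_index" in df.columns and len(df) > 0:
            si = df["seq_index"].to_numpy()
            if np.any(np.diff(si) <= 0):
                raise ValidationError("seq_index must be strictly increasing")

        roster = set(df["winner"]).union(df["loser"])
        if self.start_scores is not None:
            roster |= set(self.start_scores)
        individuals = sorted(roster, key=str)
        self.individuals_ = individuals
        index = {ind: i for i, ind in enumerate(individuals)}
        start = self._start_vector(individuals)
        kvec = k_vector(self.k)

        n = len(df)
        w_idx = np.array([index[w] for w in df["winner"]], dtype=np.intp)
        l_idx = np.array([index[l] for l in df["loser"]], dtype=np.intp)
        b_idx = behavior_codes(df["behavior"]) if n else np.empty(0, dtype=np.intp)

        scores = start.copy()
        pre_w = np.empty(n)
        pre_l = np.empty(n)
        p_exp = np.empty(n)
        delta = np.empty(n)
        rank_w = np.empty(n, dtype=np.intp)
        rank_l = np.empty(n, dtype=np.intp)
        loglik = 0.0
        day_snapshots: dict[pd.Timestamp, np.ndarray] = {}
        for i in range(n):
            w, l = w_idx[i], l_idx[i]
            ranks = dense_rank_desc(scores)
            rank_w[i], rank_l[i] = ranks[w], ranks[l]
            pre_w[i], pre_l[i] = scores[w], scores[l]
            p = win_probability(scores[w] - scores[l], self.dialect)
            p_exp[i] = p
            d = kvec[b_idx[i]] * (1.0 - p)
            delta[i] = d
            scores[w] += d
            scores[l] -= d
            loglik += np.log(p)
            day_snapshots[df["date"].iloc[i]] = scores.copy()

        self.final_scores_ = {ind: float(scores[index[ind]]) for ind in individuals}
        self.log_likelihood_ = float(loglik)
        self.events_ = pd.DataFrame(
            {
                "seq_index": (
                    df["seq_index"].to_numpy() if "seq_index" in df.columns else np.arange(n)
                ),
                "date": df["date"].to_numpy(),
                "winner": df["winner"].to_numpy(),
                "loser": df["loser"].to_numpy(),
                "behavior": df["behavior"].to_numpy(),
                "pre_winner": pre_w,
                "pre_loser": pre_l,
                "post_winner": pre_w + delta,
                "post_loser": pre_l - delta,
                "p_exp": p_exp,
                "delta": delta,
                "rank_winner": rank_w,
                "rank_loser": rank_l,
            }
        )

        if n:
            days = pd.date_range(df["date"].min(), df["date"].max(), freq="D")
            snap = pd.DataFrame(
                {d: s for d, s in day_snapshots.items()}, index=individuals
            ).T
            daily = snap.reindex(days).ffill()
            daily.iloc[0] = daily.iloc[0].fillna(pd.Series(start, index=individuals))
            daily = daily.ffill()
        else:
            daily = pd.DataFrame(columns=individuals)
        daily.index.name = "date"
        self.daily_scores_ = daily
        self.provenance_ = {
            "k": self.k,
            "start_score": self.start_score,
            "start_scores": self.start_scores,
            "dialect": self.dialect,
            "n_events": int(n),
        }
        return self

    # ------------------------------------------------------------------
    def daily_ranks(self, date) -> pd.Series:
        """Dense ranks (1 = highest score) from the end-of-day snapshot."""
        self._check_fitted()
        ts = pd.Timestamp(date)
        if len(self.daily_scores_) == 0:
            raise ValidationError("trajectory has no events")
        if ts < self.daily_scores_.index[0]:
            raise ValidationError(
                f"{ts.date()} precedes the first observation "
                f"{self.daily_scores_.index[0].date()}"
            )
        ts = min(ts, self.daily_scores_.index[-1])
        row = self.daily_scores_.loc[ts]
        return pd.Series(
            dense_rank_desc(row.to_numpy()), index=row.index, name="rank"
        )

    def predict_proba(self, pairs) -> np.ndarray:
        """P(first beats second) for an iterable of individual-id pairs,
        using the fitted final scores."""
        self._check_fitted()
        out = []
        for a, b in pairs:
            out.append(
                win_probability(
                    self.final_scores_[a] - self.final_scores_[b], self.dialect
                )
            )
        return np.asarray(out)

    def score(self, interactions: pd.DataFrame, y=None) -> float:
        """Mean per-event log-likelihood of a sequence under this config."""
        from .likelihood import sequence_log_likelihood

        ll = sequence_log_likelihood(
            interactions,
            k=self.k,
            start_score=self.start_score,
            start_scores=self.start_scores,
            dialect=self.dialect,
        )
        return ll / max(len(interactions), 1)

    def _check_fitted(self):
        if not hasattr(self, "events_"):
            raise ValidationError("EloRating instance is not fitted yet")


def compute_trajectory(
    records: pd.DataFrame,
    k=100.0,
    start_score=1000.0,
    start_scores=None,
    dialect="normal",
) -> EloRating:
    """Functional wrapper: fit and return an :class:`EloRating`."""
    return EloRating(
        k=k, start_score=start_score, start_scores=start_scores, dialect=dialect
    ).fit(records)


def daily_ranks(trajectory: EloRating, date) -> pd.Series:
    return trajectory.daily_ranks(date)
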
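"""Does body size predict interaction outcome and hierarchy position?

Two designs are built from a fitted Elo trajectory plus the biometric
series, and fitted with linear mixed models (REML):

daily
    one row per interaction; response = Elo-score difference between
    winner and loser *before* the event, predictor = difference in straight
    carapace length (SCL, cm; or weight, g) using each contestant's most
    recent measurement on or before the event date; random intercept and
    slope by winner identity.

weekly
    one row per individual per weekly interval; response = Elo-score
    difference to the week's top-ranked individual (<= 0 by construction),
    predictor = SCL difference to the week's longest individual (<= 0);
    random intercept and slope by individual identity.

Mixed models are fitted with statsmodels MixedLM under REML; fixed-effect
p-values are large-sample Wald z tests.  Singular fits (zero random
variance) are reported with ``converged=False`` rather than hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ValidationError

__all__ = [
    "build_daily_design",
    "build_weekly_design",
    "fit_mixed_model",
    "biometric_correlation",
    "SizeRankModelResult",
]


def _measurement_lookup(biometrics: pd.DataFrame, column: str):
    """Per-individual step function: most recent measurement on/before a date."""
    series = {}
    for ind, sub in biometrics.groupby("individual"):
        sub = sub.sort_values("date")
        series[ind] = (sub["date"].to_numpy(), sub[column].to_numpy(dtype=float))

    def lookup(ind, date):
        if ind not in series:
            return np.nan
        dates, vals = series[ind]
        i = np.searchsorted(dates, np.datetime64(date), side="right") - 1
        if i < 0:
            return np.nan
        return vals[i]

    return lookup


def build_daily_design(trajectory, biometrics: pd.DataFrame) -> pd.DataFrame:
    """One row per interaction with pre-event Elo and size differences.

    Rows whose contestants lack any biometric measurement on/before the
    event date are dropped with a warning; an empty result is an error.
    """
    events = getattr(trajectory, "events_", None)
    if events is None:
        raise ValidationError("build_daily_design needs a fitted EloRating")
    scl = _measurement_lookup(biometrics, "scl_cm")
    wgt = _measurement_lookup(biometrics, "weight_g")
    rows = []
    dropped = 0
    for ev in events.itertuples(index=False):
        sw, sl = scl(ev.winner, ev.date), scl(ev.loser, ev.date)
        if np.isnan(sw) or np.isnan(sl):
            dropped += 1
            continue
        ww, wl = wgt(ev.winner, ev.date), wgt(ev.loser, ev.date)
        rows.append(
            {
                "date": ev.date,
                "winner": ev.winner,
                "loser": ev.loser,
                "elo_diff_pre": ev.pre_winner - ev.pre_loser,
                "scl_diff": sw - sl,
                "weight_diff": ww - wl,
            }
        )
    if dropped:
        warnings.warn(
            f"{dropped} interactions dropped for missing biometric coverage",
            stacklevel=2,
        )
    if not rows:
        raise ValidationError("no interactions have biometric coverage")
    return pd.DataFrame(rows)


def build_weekly_design(trajectory, biometrics: pd.DataFrame, intervals) -> pd.DataFrame:
    """One row per individual per weekly interval, referenced to the week's
    top Elo score and largest SCL (both difference columns are <= 0, with
    exactly one zero per group-week per column up to ties)."""
    daily = getattr(trajectory, "daily_scores_", None)
    if daily is None:
        raise ValidationError("build_weekly_design needs a fitted EloRating")
    scl = _measurement_lookup(biometrics, "scl_cm")
    wgt = _measurement_lookup(biometrics, "weight_g")
    rows = []
    skipped = 0
    for week_index, (lo, hi) in enumerate(intervals, start=1):
        window = daily.loc[(daily.index >= lo) & (daily.index < hi)]
        if len(window) == 0:
            skipped += 1
            continue
        day = window.index[-1]  # end of week
        scores = window.iloc[-1]
        scls = {ind: scl(ind, day) for ind in daily.columns}
        wgts = {ind: wgt(ind, day) for ind in daily.columns}
        if all(np.isnan(v) for v in scls.values()):
            skipped += 1
            continue
        top = scores.max()
        longest = np.nanmax(list(scls.values()))
        heaviest = np.nanmax(list(wgts.values()))
        for ind in daily.columns:
            if np.isnan(scls[ind]):
                continue
            rows.append(
                {
                    "week_index": week_index,
                    "week_end": day,
                    "individual": ind,
                    "elo_diff_top": float(scores[ind] - top),
                    "scl_diff_max": float(scls[ind] - longest),
                    "weight_diff_max": float(wgts[ind] - heaviest),
                }
            )
    if skipped:
        warnings.warn(f"{skipped} weekly intervals skipped (no scores or SCL)", stacklevel=2)
    return pd.DataFrame(rows)


@dataclass
class SizeRankModelResult:
    """Fixed effects, Wald tests and random-effect SDs of one mixed model."""

    scope: str  # daily | weekly
    predictor: str
    grouping: str
    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float
    slope_p: float
    sd_intercept: float
    sd_slope: float
    n_obs: int
    converged: bool

    def to_row(self) -> dict:
        return {
            "scope": self.scope,
            "predictor": self.predictor,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
            "beta": self.slope,
            "beta_se": self.slope_se,
            "beta_p": self.slope_p,
            "sd_intercept": self.sd_intercept,
            "sd_slope": self.sd_slope,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def fit_mixed_model(
    design: pd.DataFrame,
    scope: str = "daily",
    predictor: str | None = None,
) -> SizeRankModelResult:
    """REML linear mixed model with random intercept + slope.

    daily scope:  elo_diff_pre ~ scl_diff, grouped by winner.
    weekly scope: elo_diff_top ~ scl_diff_max, grouped by individual.
    ``predictor`` may substitute the weight-difference column.
    """
    if scope == "daily":
        response, default_pred, grouping = "elo_diff_pre", "scl_diff", "winner"
    elif scope == "weekly":
        response, default_pred, grouping = "elo_diff_top", "scl_diff_max", "individual"
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    predictor = predictor or default_pred
    for col in (response, predictor, grouping):
        if col not in design.columns:
            raise ValidationError(f"design is missing column {col!r}")
    if design[grouping].nunique() < 2:
        raise ValidationError("mixed model needs >= 2 grouping levels")
    if len(design) < 10:
        raise ValidationError("mixed model needs >= 10 rows")

    data = design.rename(columns={response: "y", predictor: "x"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ x", data, groups=data[grouping], re_formula="~x")
        fit = model.fit(reml=True, method=["lbfgs", "cg"])
    fe = fit.fe_params
    se = fit.bse_fe
    p = fit.pvalues
    cov_re = np.asarray(fit.cov_re)
    sd_int = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    sd_slope = float(np.sqrt(max(cov_re[1, 1], 0.0))) if cov_re.shape[0] > 1 else 0.0
    converged = bool(getattr(fit, "converged", True)) and np.all(
        np.isfinite([se["Intercept"], se["x"]])
    )
    return SizeRankModelResult(
        scope=scope,
        predictor=predictor,
        grouping=grouping,
        intercept=float(fe["Intercept"]),
        intercept_se=float(se["Intercept"]),
        intercept_p=float(p["Intercept"]),
        slope=float(fe["x"]),
        slope_se=float(se["x"]),
        slope_p=float(p["x"]),
        sd_intercept=sd_int,
        sd_slope=sd_slope,
        n_obs=int(len(design)),
        converged=converged,
    )


def biometric_correlation(biometrics: pd.DataFrame):
    """Pearson correlation of SCL and weight over all paired records.

    Returns (r, p_value, n).
    """
    scl = biometrics["scl_cm"].to_numpy(dtype=float)
    wgt = biometrics["weight_g"].to_numpy(dtype=float)
    if len(scl) < 3:
        raise ValidationError("need >= 3 paired records")
    if np.std(scl) == 0 or np.std(wgt) == 0:
        raise ValidationError("zero variance in a biometric column")
    r, p = stats.pearsonr(scl, wgt)
    return float(r), float(p), int(len(scl))
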
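import warnings

import numpy as np
import pandas as pd
import pytest

from hatchrank.elo import EloRating
from hatchrank.errors import ValidationError
from hatchrank.sizerank import (
    biometric_correlation,
    build_daily_design,
    build_weekly_design,
    fit_mixed_model,
)
from hatchrank.stability import make_weekly_intervals

from conftest import random_sequence


def _bio(individuals, dates, scl_fn, weight_fn=None):
    rows = []
    for ind in individuals:
        for d in dates:
            s = scl_fn(ind, d)
            rows.append(
                {
                    "date": d,
                    "individual": ind,
                    "scl_cm": s,
                    "weight_g": weight_fn(ind, d) if weight_fn else 0.25 * s**3,
                }
            )
    return pd.DataFrame(rows)


class TestDailyDesign:
    def _setup(self):
        rows = [
            {"date": pd.Timestamp("2020-01-02"), "group": "G", "winner": "a", "loser": "b", "behavior": "HB"},
            {"date": pd.Timestamp("2020-01-03"), "group": "G", "winner": "b", "loser": "a", "behavior": "M"},
        ]
        elo = EloRating(k=10).fit(pd.DataFrame(rows))
        scl = {"a": 4.0, "b": 3.5}
        bio = _bio(["a", "b"], [pd.Timestamp("2020-01-01")], lambda i, d: scl[i])
        return elo, bio

    def test_first_event_has_zero_elo_difference(self):
        elo, bio = self._setup()
        design = build_daily_design(elo, bio)
        assert design["elo_diff_pre"].iloc[0] == 0.0
        assert design["scl_diff"].iloc[0] == pytest.approx(0.5)

    def test_row_count_matches_events_under_full_coverage(self, latent_seq):
        elo = EloRating(k=20).fit(latent_seq)
        dates = pd.date_range(latent_seq["date"].min() - pd.Timedelta(days=1), latent_seq["date"].max())
        bio = _bio(elo.individuals_, dates, lambda i, d: 4.0 + 0.1 * i)
        design = build_daily_design(elo, bio)
        assert len(design) == len(latent_seq)

    def test_most_recent_measurement_is_used(self):
        elo, _ = self._setup()
        bio = _bio(
            ["a", "b"],
            [pd.Timestamp("2020-01-01"), pd.Timestamp("2020-01-03")],
            lambda i, d: (4.0 if i == "a" else 3.5) + (1.0 if d.day == 3 else 0.0),
        )
        design = build_daily_design(elo, bio)
        # day 2 event uses day-1 values, day 3 event uses day-3 values
        assert design["scl_diff"].tolist() == pytest.approx([0.5, -0.5])

    def test_uncovered_rows_dropped_with_warning(self):
        rows = [
            {"date": pd.Timestamp("2020-01-02"), "group": "G", "winner": "a", "loser": "b", "behavior": "HB"},
            {"date": pd.Timestamp("2020-01-03"), "group": "G", "winner": "a", "loser": "c", "behavior": "M"},
        ]
        elo = EloRating(k=10).fit(pd.DataFrame(rows))
        scl = {"a": 4.0, "b": 3.5}
        bio = _bio(["a", "b"], [pd.Timestamp("2020-01-01")], lambda i, d: scl[i])
        with pytest.warns(UserWarning, match="dropped"):
            design = build_daily_design(elo, bio)  # c never measured
        assert len(design) == 1

    def test_no_coverage_at_all_rejected(self):
        elo, bio = self._setup()
        late = bio.assign(date=pd.Timestamp("2021-01-01"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValidationError, match="coverage"):
                build_daily_design(elo, late)

    def test_antisymmetry_under_winner_loser_relabeling(self, latent_seq):
        """Swapping the winner/loser roles in the event log flips the sign
        of both design columns (the trajectory itself is held fixed)."""
        elo = EloRating(k=20).fit(latent_seq)
        dates = pd.date_range(latent_seq["date"].min() - pd.Timedelta(days=1), latent_seq["date"].max())
        rng = np.random.default_rng(0)
        scl = {i: 4 + rng.normal(0, 0.4) for i in elo.individuals_}
        bio = _bio(elo.individuals_, dates, lambda i, d: scl[i])
        d1 = build_daily_design(elo, bio)

        from types import SimpleNamespace

        swapped_events = elo.events_.rename(
            columns={
                "winner": "loser",
                "loser": "winner",
                "pre_winner": "pre_loser",
                "pre_loser": "pre_winner",
            }
        )
        d2 = build_daily_design(SimpleNamespace(events_=swapped_events), bio)
        assert np.allclose(d1["elo_diff_pre"], -d2["elo_diff_pre"])
        assert np.allclose(d1["scl_diff"], -d2["scl_diff"])


class TestWeeklyDesign:
    def _fit(self, n_weeks=5):
        df = random_sequence(240, n_individuals=5, seed=21)
        elo = EloRating(k=20).fit(df)
        intervals = make_weekly_intervals(
            df["date"].min(), df["date"].max() + pd.Timedelta(days=1), n_weeks
        )
        return df, elo, intervals

    def test_row_budget_and_references(self):
        df, elo, intervals = self._fit()
        dates = pd.date_range(df["date"].min() - pd.Timedelta(days=1), df["date"].max())
        rng = np.random.default_rng(1)
        scl = {i: 4 + rng.normal(0, 0.4) for i in elo.individuals_}
        bio = _bio(elo.individuals_, dates, lambda i, d: scl[i])
        design = build_weekly_design(elo, bio, intervals)
        assert len(design) <= 5 * len(intervals)
        assert (design["elo_diff_top"] <= 1e-12).all()
        assert (design["scl_diff_max"] <= 1e-12).all()
        for _, week in design.groupby("week_index"):
            assert (week["elo_diff_top"] == 0).sum() >= 1
            assert (week["scl_diff_max"] == 0).sum() >= 1

    def test_matched_orders_give_positive_correlation(self):
        df, elo, intervals = self._fit()
        # SCL ordered exactly like the final Elo order, constant in time
        final_order = sorted(elo.final_scores_, key=elo.final_scores_.get)
        scl = {ind: 3.5 + 0.2 * i for i, ind in enumerate(final_order)}
        dates = pd.date_range(df["date"].min() - pd.Timedelta(days=1), df["date"].max())
        bio = _bio(elo.individuals_, dates, lambda i, d: scl[i])
        design = build_weekly_design(elo, bio, intervals)
        r = np.corrcoef(design["elo_diff_top"], design["scl_diff_max"])[0, 1]
        assert r > 0


class TestMixedModel:
    @staticmethod
    def _simulate_design(slope=-30.0, noise_sd=20.0, n_winners=6, rows_per=100,
                         re_int_sd=10.0, re_slope_sd=2.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for w in range(n_winners):
            b0 = rng.normal(0, re_int_sd)
            b1 = rng.normal(0, re_slope_sd)
            x = rng.normal(0, 1.0, rows_per)
            y = (b0) + (slope + b1) * x + rng.normal(0, noise_sd, rows_per)
            for xi, yi in zip(x, y):
                rows.append({"winner": f"w{w}", "scl_diff": xi, "elo_diff_pre": yi})
        return pd.DataFrame(rows)

    def test_recovers_generating_slope(self):
        design = self._simulate_design(seed=42)
        res = fit_mixed_model(design, "daily")
        assert abs(res.slope - (-30.0)) < 2 * res.slope_se
        assert res.slope_se > 0
        assert 0 < res.slope_p <= 1
        assert res.n_obs == len(design)

    def test_zero_response_gives_zero_estimates(self):
        design = self._simulate_design(seed=1)
        design["elo_diff_pre"] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_mixed_model(design, "daily")
        assert res.intercept == pytest.approx(0.0, abs=1e-6)
        assert res.slope == pytest.approx(0.0, abs=1e-6)

    def test_no_grouping_variance_reduces_to_ols(self):
        design = self._simulate_design(re_int_sd=0.0, re_slope_sd=0.0, seed=3)
        res = fit_mixed_model(design, "daily")
        slope_ols, intercept_ols = np.polyfit(design["scl_diff"], design["elo_diff_pre"], 1)
        assert res.slope == pytest.approx(slope_ols, abs=0.5)
        assert res.intercept == pytest.approx(intercept_ols, abs=0.5)

    def test_too_few_groups_or_rows_rejected(self):
        design = self._simulate_design(n_winners=1)
        with pytest.raises(ValidationError, match="grouping"):
            fit_mixed_model(design, "daily")
        design2 = self._simulate_design(rows_per=2, n_winners=2)
        with pytest.raises(ValidationError, match="rows"):
            fit_mixed_model(design2, "daily")

    def test_weekly_scope_column_mapping(self):
        design = self._simulate_design(seed=5).rename(
            columns={"winner": "individual", "scl_diff": "scl_diff_max", "elo_diff_pre": "elo_diff_top"}
        )
        res = fit_mixed_model(design, "weekly")
        assert res.scope == "weekly" and res.grouping == "individual"


class TestBiometricCorrelation:
    def test_exact_linear_relation(self):
        bio = pd.DataFrame(
            {"scl_cm": [3.5, 4.0, 4.5, 5.0], "weight_g": [7.0, 8.0, 9.0, 10.0]}
        )
        r, p, n = biometric_correlation(bio)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 4

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        bio = pd.DataFrame(
            {"scl_cm": rng.uniform(3, 7, 2000), "weight_g": rng.uniform(10, 80, 2000)}
        )
        r, _, n = biometric_correlation(bio)
        assert abs(r) < 0.1 and n == 2000

    def test_zero_variance_rejected(self):
        bio = pd.DataFrame({"scl_cm": [4.0, 4.0, 4.0], "weight_g": [8, 9, 10]})
        with pytest.raises(ValidationError, match="variance"):
            biometric_correlation(bio)

    def test_too_few_records_rejected(self):
        bio = pd.DataFrame({"scl_cm": [4.0, 4.1], "weight_g": [8, 9]})
        with pytest.raises(ValidationError):
            biometric_correlation(bio)
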
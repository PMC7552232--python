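import math

import numpy as np
import pandas as pd
import pytest

from hatchrank.errors import ConfigurationError, ValidationError
from hatchrank.likelihood import (
    ConstantKMLE,
    OptimizationResult,
    PerBehaviorKMLE,
    StartValueMLE,
    compare_models,
    optimize_constant_k,
    optimize_per_behavior_k,
    optimize_start_values,
    sequence_log_likelihood,
)
from hatchrank.simulate import simulate_latent_sequence

from _reference import ref_trajectory
from conftest import random_sequence


def _one_group(rows):
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    df["group"] = "G"
    df["seq_index"] = np.arange(len(df))
    return df


class TestSequenceLogLikelihood:
    def test_single_event_between_newcomers_is_log_half(self):
        df = _one_group([{"date": "2020-01-01", "winner": 1, "loser": 2, "behavior": "HB"}])
        assert sequence_log_likelihood(df, k=50) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_two_step_hand_fold(self):
        # k = 100, logistic: first event ln 0.5; the winner then leads by 100,
        # so the second term is ln(1/(1+10^(−100/400)))
        df = _one_group(
            [
                {"date": "2020-01-01", "winner": 1, "loser": 2, "behavior": "HB"},
                {"date": "2020-01-01", "winner": 1, "loser": 2, "behavior": "HB"},
            ]
        )
        expected = math.log(0.5) + math.log(1.0 / (1.0 + 10 ** (-100.0 / 400.0)))
        got = sequence_log_likelihood(df, k=100, dialect="logistic")
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-1.13933, abs=1e-5)

    def test_empty_sequence_warns_and_returns_zero(self):
        empty = pd.DataFrame(columns=["date", "winner", "loser", "behavior"])
        with pytest.warns(UserWarning, match="empty"):
            assert sequence_log_likelihood(empty, k=10) == 0.0

    @pytest.mark.parametrize("dialect", ["normal", "logistic"])
    def test_matches_brute_force_reference(self, dialect):
        df = random_sequence(250, seed=5)
        k = {"HB": 12, "M": 18, "TB": 5}
        _, _, ref_ll = ref_trajectory(
            list(zip(df["winner"], df["loser"], df["behavior"])), k, dialect=dialect
        )
        assert sequence_log_likelihood(df, k=k, dialect=dialect) == pytest.approx(
            ref_ll, abs=1e-9
        )

    def test_repeated_calls_bit_identical(self, latent_seq):
        a = sequence_log_likelihood(latent_seq, k=17)
        b = sequence_log_likelihood(latent_seq, k=17)
        assert a == b


class TestConstantK:
    def test_default_grid_is_integers_1_to_200(self, latent_seq):
        fit = ConstantKMLE().fit(latent_seq)
        assert fit.n_evaluations_ == 200
        assert np.allclose(fit.grid_["param"], np.arange(1, 201))
        assert fit.result_.max_loglik == fit.grid_["loglik"].max()
        assert fit.result_.max_loglik <= 0

    def test_recovers_generating_k(self):
        df = simulate_latent_sequence(1000, 6, k_true=30, seed=123)
        fit = ConstantKMLE().fit(df)
        assert abs(fit.best_k_ - 30) <= 8

    def test_ties_break_toward_smaller_k(self):
        # a single event scores ln 0.5 for every k, so the whole grid ties
        df = _one_group([{"date": "2020-01-01", "winner": 1, "loser": 2, "behavior": "HB"}])
        assert ConstantKMLE().fit(df).best_k_ == 1.0

    def test_degenerate_range_rejected(self, latent_seq):
        with pytest.raises(ConfigurationError):
            ConstantKMLE(k_range=(5, 5)).fit(latent_seq)
        with pytest.raises(ConfigurationError):
            ConstantKMLE(n_grid=1).fit(latent_seq)


class TestPerBehaviorK:
    def test_single_behavior_reduces_to_constant(self):
        df = simulate_latent_sequence(
            300, 5, k_true=25, seed=9, behavior_probs={"HB": 1.0, "M": 0.0, "TB": 0.0}
        )
        const = ConstantKMLE().fit(df)
        with pytest.warns(UserWarning, match="absent"):
            perbeh = PerBehaviorKMLE().fit(df)
        assert perbeh.max_loglik_ == pytest.approx(const.max_loglik_, abs=1e-9)
        assert perbeh.best_k_["HB"] == const.best_k_

    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_property(self, seed):
        df = simulate_latent_sequence(400, 6, k_true=15, seed=1000 + seed)
        const = ConstantKMLE().fit(df)
        perbeh = PerBehaviorKMLE().fit(df)
        assert perbeh.max_loglik_ >= const.max_loglik_ - 1e-9

    def test_profile_curves_exported(self, latent_seq):
        fit = PerBehaviorKMLE().fit(latent_seq)
        assert set(fit.profile_curves_) == {"HB", "M", "TB"}
        for beh, curve in fit.profile_curves_.items():
            assert list(curve.columns) == ["param", "loglik"]
            # each profile curve attains the joint maximum at the chosen k
            assert curve["loglik"].max() <= fit.max_loglik_ + 1e-9

    def test_full_grid_agrees_on_coarse_grid(self):
        df = simulate_latent_sequence(150, 5, k_true=20, seed=4)
        coarse = dict(k_range=(1.0, 200.0), n_grid=8)
        prof = PerBehaviorKMLE(**coarse, strategy="profile").fit(df)
        full = PerBehaviorKMLE(**coarse, strategy="full_grid").fit(df)
        assert full.max_loglik_ >= prof.max_loglik_ - 1e-9


class TestStartValues:
    def test_tiny_spread_reproduces_baseline(self, latent_seq):
        fit = StartValueMLE(k=20, n_draws=1, spread=1e-9, random_state=0).fit(latent_seq)
        assert fit.max_loglik_ == pytest.approx(fit.baseline_loglik_, abs=1e-6)

    def test_nonpositive_spread_rejected(self, latent_seq):
        with pytest.raises(ConfigurationError):
            StartValueMLE(k=20, spread=0.0).fit(latent_seq)

    def test_draws_recentred_to_mean_1000(self, latent_seq):
        fit = StartValueMLE(k=20, n_draws=50, spread=200, random_state=1).fit(latent_seq)
        grid = fit.result_.evaluation_grid
        means = grid.drop(columns="loglik").mean(axis=1)
        assert np.allclose(means, 1000.0, atol=1e-9)
        assert fit.n_evaluations_ == 51  # 50 draws + all-equal baseline

    def test_seeded_reproducibility(self, latent_seq):
        a = StartValueMLE(k=20, n_draws=100, random_state=7).fit(latent_seq)
        b = StartValueMLE(k=20, n_draws=100, random_state=7).fit(latent_seq)
        assert a.best_starts_ == b.best_starts_
        assert a.max_loglik_ == b.max_loglik_

    def test_null_improvement_within_chi_square_envelope(self):
        """Data generated from equal true starts: the best-of-2000 draw can
        only beat the all-1000 baseline by overfitting the 5 free relative
        start values, so twice the gain is bounded by a chi-square with 5
        degrees of freedom.  Assert every replicate sits below the 0.995
        quantile (16.7/2 ≈ 8.4 log units) and the replicate median below
        twice the chi-square median (4.35/2 · 2 ≈ 4.3)."""
        gains = []
        for rep in range(20):
            df = simulate_latent_sequence(1000, 6, k_true=15, seed=7000 + rep)
            k_hat = ConstantKMLE().fit(df).best_k_
            fit = StartValueMLE(k=k_hat, n_draws=2000, random_state=rep).fit(df)
            gains.append(fit.max_loglik_ - fit.baseline_loglik_)
        assert all(g >= 0 for g in gains)  # baseline is always in the grid
        assert max(gains) < 8.4
        assert np.median(gains) < 4.3


class TestCompareModels:
    def _result(self, mode, ll, n_params=1, n_events=500, dialect="normal"):
        return OptimizationResult(
            mode=mode,
            best_params={},
            max_loglik=ll,
            evaluation_grid=pd.DataFrame(),
            n_events=n_events,
            dialect=dialect,
            n_params=n_params,
        )

    def test_identical_results_have_zero_delta(self):
        r = self._result("constant_k", -476.5)
        table = compare_models([r, r])
        assert (table["delta_loglik"] == 0).all()

    def test_printed_group_one_pair_delta(self):
        # arithmetic on the two reported maxima: −473.6 vs −476.5
        table = compare_models(
            [
                self._result("constant_k", -476.5, n_params=1),
                self._result("per_behavior_k", -473.6, n_params=3),
            ]
        )
        row = table[table["model"] == "constant_k"].iloc[0]
        assert row["delta_loglik"] == pytest.approx(2.9, abs=1e-9)

    def test_parsimony_flag_prefers_fewer_params_within_threshold(self):
        table = compare_models(
            [
                self._result("constant_k", -476.5, n_params=1),
                self._result("per_behavior_k", -476.0, n_params=3),
            ]
        )
        assert table.loc[table["most_parsimonious"], "model"].tolist() == ["constant_k"]

    def test_mismatched_provenance_rejected(self):
        with pytest.raises(ValidationError, match="same records"):
            compare_models(
                [
                    self._result("constant_k", -100.0, n_events=500),
                    self._result("per_behavior_k", -99.0, n_events=400),
                ]
            )

    def test_loglik_above_zero_rejected(self):
        with pytest.raises(ValidationError):
            self._result("constant_k", 1.0)


def test_functional_wrappers_match_estimators(latent_seq):
    r1 = optimize_constant_k(latent_seq)
    r2 = ConstantKMLE().fit(latent_seq).result_
    assert r1.best_params == r2.best_params and r1.max_loglik == r2.max_loglik
    r3 = optimize_per_behavior_k(latent_seq)
    assert r3.mode == "per_behavior_k"
    r4 = optimize_start_values(latent_seq, k=r1.best_params["k"], n_draws=10, seed=3)
    assert r4.mode == "start_values" and r4.n_evaluations == 11
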
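# hatchrank

Dominance-hierarchy inference for small cohorts of dyadically interacting
animals, built around sequential Elo rating.

Behavioral studies of captive-reared hatchlings (the motivating system is
groups of 5–6 European pond turtle hatchlings observed daily over their
first months of life) record long chronological sequences of dyadic
agonistic events — head bites, tail bites, mounts — each with an
unambiguous winner and loser. `hatchrank` turns such a sequence, plus a
daily biometric table, into a quantitative description of the group's
social structure:

* **Elo trajectories.** Each individual starts at a score of 1000; after
  every event the winner gains and the loser loses
  `k · (1 − E)`, where `E` is the expected win probability of the realized
  winner given the pre-event score difference `d`. Two expectation
  dialects are supported: `E = Φ(d / (200·√2))` (normal, the default) and
  `E = 1 / (1 + 10^(−d/400))` (logistic).
* **Maximum-likelihood fitting of k and starting scores.** The
  winner-sequence log-likelihood `LL = Σₜ ln E(winner_t)` is maximized over
  a 200-point grid of k on [1, 200] (a single shared k, or one k per
  behavior type via coordinate-wise profile search), and over randomized
  per-individual starting scores (2000 draws on 1000 ± 200, recentred).
  Competing parameterizations are compared by their maximum
  log-likelihoods.
* **Hierarchy stability.** A weekly stability index S ∈ [0, 1] weighting
  day-to-day dense-rank changes by the standardized Elo score of the
  individual that moved; S = 1 means a change-free week, a complete daily
  reversal scores 0.
* **Hierarchy steepness.** P(higher-ranked contestant wins) as a function
  of the pre-event rank difference, aggregated over cumulative monthly
  periods and summarized by a two-parameter logistic fit.
* **Size–rank models.** Linear mixed models (REML, random intercept +
  slope) testing whether the difference in straight carapace length (SCL)
  or weight predicts the pre-event Elo difference (daily scale) or the
  distance to the top of the hierarchy (weekly scale), plus the SCL–weight
  allometric correlation.
* **A seeded synthetic-data generator** that emulates the whole study —
  latent-Elo outcomes, session calendar, behavior mixture, logistic growth
  and allometric weight — so every stage is testable without any download.

## Worked example

```python
import pandas as pd
import hatchrank as hr

cfg = hr.SyntheticConfig(seed=7, k_true=11.0)          # 3 groups, 7 months
cohort, interactions, biometrics = hr.generate_dataset(cfg)
g1 = interactions[interactions["group"] == "G1"].reset_index(drop=True)

const = hr.ConstantKMLE().fit(g1)
perbeh = hr.PerBehaviorKMLE().fit(g1)
print(f"best constant k = {const.best_k_:.0f}   logLik = {const.max_loglik_:.1f}")
print(f"best per-behavior k = {perbeh.best_k_}   logLik = {perbeh.max_loglik_:.1f}")

elo = hr.EloRating(k=const.best_k_).fit(g1)
weeks = hr.make_weekly_intervals(g1["date"].min(),
                                 g1["date"].max() + pd.Timedelta(days=1), 30)
stab = hr.stability_series(elo, weeks)
print(f"weekly stability index: median {stab['S'].median():.3f}, min {stab['S'].min():.3f}")

period = (g1["date"].min(), g1["date"].max() + pd.Timedelta(days=1))
curve = hr.winner_prob_curve(elo, period)
print(f"steepness slope = {curve.fit_slope:.3f}  P(win | rank diff 4) = {curve.predict(4):.3f}")

r, p, n = hr.biometric_correlation(biometrics)
print(f"SCL-weight Pearson r = {r:.3f} (n = {n})")
```

Output:

```
best constant k = 18   logLik = -521.7
best per-behavior k = {'HB': 16.0, 'M': 22.0, 'TB': 8.0}   logLik = -521.3
weekly stability index: median 0.970, min 0.788
steepness slope = 0.425  P(win | rank diff 4) = 0.828
SCL-weight Pearson r = 0.974 (n = 2432)
```

Reading: the grid-ML update constant for this simulated group is k = 18,
and letting k differ by behavior buys only 0.4 log-likelihood units for two
extra parameters, so the constant-k model is preferred. The hierarchy is
stable (S stays near 1 after the settling-in weeks) but fairly flat: the
probability that the higher-ranked animal wins rises to only ≈ 0.83 at the
largest rank difference. Weight tracks shell length almost deterministically
(r = 0.97), as the allometric generator intends.

The same analysis runs from the shell on CSV inputs
(`interactions.csv`: `date,group,winner,loser,behavior`;
`biometrics.csv`: `date,individual,scl_cm,weight_g`):

```bash
hatchrank simulate --seed 7 --out data/
hatchrank run --interactions data/interactions.csv \
              --biometrics data/biometrics.csv --out results/run1
hatchrank report results/run1 --plots
```

`run` writes per-group CSV tables (trajectories, event logs, k grids,
model comparisons, stability series, steepness curves, mixed-model
results, dyad edge lists) and a `manifest.json` with seeds, the dialect
and SHA-256 hashes of every output, so re-runs are verifiable
byte-for-byte.

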
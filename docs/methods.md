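# Methods

## The rating model

A group of n individuals interacts in a chronological sequence of dyadic
agonistic events, each with a winner, a loser and a behavior label
(HB head bite, TB tail bite, M mount; no draws). Every individual carries a
score, initialized at 1000, and after each event

    winner += k · (1 − E),    loser −= k · (1 − E),

where E is the expected win probability of the realized winner computed
from the pre-event score difference d. The update is zero-sum, so with
equal starting scores the group total n·1000 is conserved exactly (the
test suite checks this to 1e-9).

Two expectation dialects are implemented, because both are in common use
and published analyses rarely state which one they used:

* `normal` (default): E = Φ(d / (200·√2)). One "class interval" is 200
  rating points; the difference of two independent performances then has
  SD 200·√2.
* `logistic`: E = 1 / (1 + 10^(−d/400)), the classic chess convention.

At d = 0 both give exactly 0.5; they differ by < 0.01 over the score
ranges these data produce. The dialect is recorded in every trajectory's
provenance and in the run manifest; reproductions of published numbers
should be attempted under both.

Within-day event order is not observable in the input format (dates carry
no timestamps), so file order within a date is frozen as the canonical
sequence and recorded in the table's metadata. Elo is sequence-sensitive;
any deterministic convention is better than an undocumented one.

## Fitting k and starting scores

The objective is the winner-sequence log-likelihood
LL = Σₜ ln E(winner_t), evaluated along the sequential trajectory (the
state entering event t reflects events 1..t−1). LL ≤ 0 always; the first
meeting of two newcomers contributes exactly ln 0.5.

* **Constant k**: grid search over 200 uniform points on [1, 200] — i.e.
  the integers 1..200 at the defaults. Ties break toward the smaller k.
  The grid, not a continuous optimizer, is the method: the likelihood
  surface in k is cheap to evaluate in one vectorized pass (a batch axis
  over candidates shares the single sweep over events), and the grid
  resolution is itself a documented, configurable quantity.
* **Per-behavior k** (k_HB, k_M, k_TB): coordinate-wise profile search on
  the same grid, initialized at the constant-k optimum and swept to a
  fixed point (max 10 sweeps; in practice 2–3). Because the initialization
  point lies on the first coordinate grid, the attained maximum can never
  fall below the constant-k maximum — the nesting property the model
  comparison relies on. A full 200³ grid would buy nothing for three
  orders of magnitude more work; a `full_grid` strategy exists for coarse
  grids and is used as a cross-check in tests. The per-coordinate profile
  curves (LL vs k with the other two coordinates at their optima) are
  exported for the visual model comparison.
* **Starting scores**: 2000 i.i.d. draws of per-individual starts, uniform
  on 1000 ± 200, each vector recentred to mean 1000 (the likelihood
  depends only on relative starts), evaluated in one vectorized pass; the
  all-equal baseline is always evaluated alongside. Under the null of
  truly equal starts, twice the best-draw gain is bounded by a χ² with
  n−1 degrees of freedom — the suite asserts that envelope rather than a
  tighter ad-hoc constant, since the expected null gain for a 6-animal
  group is already ≈ 2.5 log units.

Model comparison is by raw maximum log-likelihoods (no information
criteria): a table of Δ-to-best values flags the most parsimonious model
within a configurable threshold (default 2 log units).

**Recovery performance.** On simulated data at study scale (1000 events,
6 individuals, equal starts, normal dialect) the grid-ML estimate of k is
unbiased with sampling SD ≈ 4 at k = 10 and proportionally tighter in
relative terms at larger k; the acceptance suite requires the 20-replicate
median error within 20% of the generating k at k ∈ {10, 30, 80}. The
k = 10 case is the marginal one — 20% of 10 is only half the sampling SD —
and sits right at that bound at this sample size.

## Stability index

For each weekly interval (30 contiguous half-open 7-day windows by
default, anchored at the first observation; the last window absorbs the
remainder), scores are carried forward day-to-day as a step function, so
rank changes can only occur across interaction days. For each consecutive
day pair, each individual contributes its absolute dense-rank change
weighted by its min–max-standardized score on the earlier day (changes at
the top of the hierarchy weigh more). S = 1 − observed/maximal, where the
maximal weighted change for a day pair is the one a complete top-to-bottom
reversal would produce under the same weights. Hence S = 1 exactly for a
change-free interval, 0 for daily full reversals, and appending a
change-free day can only raise S. A deliberately slow reference
implementation (explicit loops over day pairs and individuals) pins the
statistic in the tests to 1e-9.

## Steepness

Hierarchy steepness is the curve of P(higher-ranked contestant wins)
against the pre-event rank difference d ∈ {1..n−1}, pooled over cumulative
monthly periods (start→+1mo, start→+2mo, …, whole span) so its temporal
evolution is visible. Ranks are dense ranks of the scores immediately
before each event — same-day earlier events count, which matters for a
sequence-sensitive rating. Rank-tied events carry no direction; they are
excluded from the curve and reported as a separate count.

The summary fit is a two-parameter logistic in d, estimated by binomial
maximum likelihood on the event-level outcomes. The optimizer is bounded
(|intercept|, |slope| ≤ 30) so perfectly decided data (every
higher-ranked animal wins) yield a saturated, flagged fit rather than a
separation failure; on well-conditioned data the estimates agree with an
IRLS GLM to 1e-4 (asserted in the tests). The curve family is a summary
device, not a claim about mechanism; comparisons across periods are
qualitative.

## Size–rank models

Daily scale: one row per interaction, response = winner-minus-loser Elo
difference before the event, predictor = SCL (or weight) difference using
each contestant's most recent measurement on/before the event date (no
interpolation; measurements are near-daily so gaps are small). Weekly
scale: one row per individual per weekly interval, response = Elo distance
to the week's top score (≤ 0), predictor = SCL distance to the week's
longest animal (≤ 0). Models are linear mixed models fitted by REML with
random intercept and slope by winner (daily) or individual (weekly),
via statsmodels MixedLM. Fixed-effect p-values are large-sample Wald z
tests; small-sample degrees-of-freedom corrections (Satterthwaite/
Kenward–Roger) are not available in this backend, which shifts p-values
slightly for the ~5–6 grouping levels these designs have — estimates and
SEs are unaffected, and singular or non-converged fits are flagged, never
silently accepted. SCL and weight are analyzed separately (they are
nearly collinear: allometric r ≈ 0.97).

## Synthetic data

The generator emulates the statistical structure of the motivating study,
with defaults frozen at its conditions:

| parameter | default | meaning |
|---|---|---|
| group_sizes | (6, 5, 5) | three tanks of same-age hatchlings |
| span | 7 months from 2017-11-01, 5 sessions/week | observation calendar |
| events_per_session_mean | 6 (Poisson) | ≈ 700–950 events per group over the span |
| behavior_probs | HB 0.74 / M 0.22 / TB 0.04 | observed mixture ranges HB 67–80%, M 15–29%, TB < 4% |
| k_true | 11 | latent update constant (the scale the study's fits landed on) |
| start_spread | 0 | latent start scores 1000 ± spread; 0 = flat initial hierarchy |
| dyad_choice | uniform | `propensity` mode draws per-individual Dirichlet weights to reproduce the very unequal per-individual totals real data show |
| SCL growth | logistic, 3.75 → 6.75 cm (SD 0.49/0.67) | monotone per-individual curve, measurement noise SD 0.002 cm (below daily increments) |
| weight law | W = 0.25·SCL³·exp(ε), ε ~ N(0, 0.05) | gives SCL–W Pearson r ≈ 0.97 |

Winners are realized as Bernoulli draws of the expectation probability of
the current *true* scores, which then update with k_true — so constant-k
ML estimation on the output is a well-posed recovery problem, and
`start_spread` is the steepness dial (wider latent gaps → steeper fitted
curves, asserted monotone in the tests). By default the generator and the
inference use the same expectation dialect; a mismatch can be configured
to probe robustness.

What the generator does **not** emulate: temporal drift in interaction
propensity, coalitions, winner/loser effects beyond the Elo update,
seasonal growth plateaus, observation error in winner identity. Passing
recovery tests therefore show the estimators are correct *under the
model's own assumptions*, not that real hatchling data satisfy them.

## Problem sizes and numerical choices

The test and acceptance workloads use 120–1500-event sequences, 20
replicates per recovery experiment and the full 7-month generator for
study-scale checks — sizes at which every result above is stable and the
whole suite runs in well under a minute per module. Log-likelihood
evaluations are deterministic and bit-reproducible; all simulation draws
go through seeded `numpy` generators (per-stage child seeds derived from
one master seed), and the pipeline manifest records seeds, dialect and
output hashes so a re-run is verifiable byte-for-byte. Dense ranks break
ties by sharing the smallest rank of the tied block; exact score ties are
measure-zero but the convention keeps every downstream statistic
deterministic. Dates are ISO-8601; a day-first parser exists only behind
an explicit flag, never auto-detected.

## Known limitations

* The stability index's weighting follows the package's frozen definition
  (standardized score of the individual that moved); other published
  variants weight by the higher-rated individual involved in a swap and
  can differ in the second decimal on real data.
* Wald-z p-values in the mixed models are anti-conservative for designs
  with few grouping levels; treat borderline p-values accordingly.
* The steepness logistic is fitted to pooled events within a period;
  events are not independent (the rating that defines the ranks is itself
  estimated from them), so its SEs are not reported.
* Start-value optimization explores 1000 ± 200 by random search; it finds
  the neighborhood of the optimum, not the exact ML start vector, which is
  the intended use (testing for an unobserved prior hierarchy, not point
  estimation).
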
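"""Winner-sequence likelihood and maximum-likelihood fitting of Elo parameters.

The objective throughout is the winner-sequence log-likelihood

    LL(k, starts) = sum over events of ln P(realized winner | pre-event scores)

computed along the *sequential* trajectory, so the score state that enters
event t already reflects events 1..t−1.  Three fitted-parameter modes are
provided, each as a scikit-learn style estimator plus a functional wrapper:

ConstantKMLE
    grid search of a single shared k over [1, 200] at 200 grid points
    (integer k at the defaults); ties broken toward smaller k.
PerBehaviorKMLE
    coordinate-wise (profile) grid maximization of (k_HB, k_M, k_TB),
    initialized at the constant-k optimum and iterated to a fixed point.
    Because the initialization point is on the profile grid, the attained
    maximum can never fall below the constant-k maximum (nesting).
StartValueMLE
    randomized search over per-individual starting scores: n_draws vectors
    drawn i.i.d. uniform on 1000 ± spread per individual, each recentred to
    mean 1000 (only relative starts matter for the sequence likelihood).

All searches are single passes of :func:`hatchrank._core.fold_sequence`
with the candidate axis vectorized, so a 200-point k grid or 2000 start
vectors cost one sweep over the events each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._core import BEHAVIORS, behavior_codes, fold_sequence, k_vector
from .errors import ConfigurationError, ValidationError

__all__ = [
    "OptimizationResult",
    "sequence_log_likelihood",
    "ConstantKMLE",
    "PerBehaviorKMLE",
    "StartValueMLE",
    "optimize_constant_k",
    "optimize_per_behavior_k",
    "optimize_start_values",
    "compare_models",
]


@dataclass
class OptimizationResult:
    """Outcome of one likelihood optimization run."""

    mode: str  # constant_k | per_behavior_k | start_values
    best_params: object
    max_loglik: float
    evaluation_grid: pd.DataFrame = field(repr=False)
    n_evaluations: int = 0
    seed: int | None = None
    dialect: str = "normal"
    n_events: int = 0
    n_params: int = 1
    baseline_loglik: float | None = None

    def __post_init__(self):
        if self.max_loglik > 1e-12:
            raise ValidationError(
                f"log-likelihood must be <= 0, got {self.max_loglik}"
            )


def _prepare(records: pd.DataFrame):
    individuals = sorted(set(records["winner"]).union(records["loser"]), key=str)
    index = {ind: i for i, ind in enumerate(individuals)}
    w = np.array([index[x] for x in records["winner"]], dtype=np.intp)
    l = np.array([index[x] for x in records["loser"]], dtype=np.intp)
    b = behavior_codes(records["behavior"])
    return individuals, w, l, b


def _start_vector(individuals, start_score, start_scores):
    if start_scores is None:
        return np.full(len(individuals), float(start_score))
    missing = [i for i in individuals if i not in start_scores]
    if missing:
        raise ConfigurationError(f"start_scores missing individuals {missing!r}")
    return np.array([float(start_scores[i]) for i in individuals])


def sequence_log_likelihood(
    records: pd.DataFrame,
    k=100.0,
    start_score: float = 1000.0,
    start_scores=None,
    dialect: str = "normal",
) -> float:
    """Sum over events of ln P(realized winner), along the sequential
    trajectory.  Deterministic given inputs; an empty sequence returns 0
    (the log of an empty product) with a warning."""
    if len(records) == 0:
        warnings.warn("empty interaction sequence: log-likelihood is 0", stacklevel=2)
        return 0.0
    individuals, w, l, b = _prepare(records)
    start = _start_vector(individuals, start_score, start_scores)
    ll = fold_sequence(w, l, b, k_vector(k), start, dialect)
    return float(ll[0])


def _k_grid(k_range, n_grid) -> np.ndarray:
    lo, hi = float(k_range[0]), float(k_range[1])
    if not (hi > lo > 0):
        raise ConfigurationError(f"degenerate k range {k_range!r}")
    if n_grid < 2:
        raise ConfigurationError("n_grid must be >= 2")
    return np.linspace(lo, hi, int(n_grid))


class ConstantKMLE(BaseEstimator):
    """Maximum-likelihood constant k by grid search.

    The default grid is 200 uniform points on [1, 200], i.e. the integers
    1..200.  Ties are broken toward the smaller k.

    Attributes (after fit): ``best_k_``, ``max_loglik_``, ``grid_``
    (DataFrame of k vs loglik), ``result_`` (:class:`OptimizationResult`).
    """

    def __init__(
        self,
        k_range=(1.0, 200.0),
        n_grid=200,
        start_score=1000.0,
        start_scores=None,
        dialect="normal",
    ):
        self.k_range = k_range
        self.n_grid = n_grid
        self.start_score = start_score
        self.start_scores = start_scores
        self.dialect = dialect

    def fit(self, records: pd.DataFrame, y=None):
        if len(records) == 0:
            raise ValidationError("cannot optimize k on an empty sequence")
        ks = _k_grid(self.k_range, self.n_grid)
        individuals, w, l, b = _prepare(records)
        start = _start_vector(individuals, self.start_score, self.start_scores)
        k_matrix = np.repeat(ks[:, None], 3, axis=1)
        ll = fold_sequence(w, l, b, k_matrix, start, self.dialect)
        best = int(np.argmax(ll))  # argmax returns the first (smallest-k) maximum
        self.best_k_ = float(ks[best])
        self.max_loglik_ = float(ll[best])
        self.grid_ = pd.DataFrame({"param": ks, "loglik": ll})
        self.n_evaluations_ = len(ks)
        self.result_ = OptimizationResult(
            mode="constant_k",
            best_params={"k": self.best_k_},
            max_loglik=self.max_loglik_,
            evaluation_grid=self.grid_,
            n_evaluations=self.n_evaluations_,
            dialect=self.dialect,
            n_events=len(records),
            n_params=1,
        )
        return self


class PerBehaviorKMLE(BaseEstimator):
    """Profile (coordinate-wise) ML search of behavior-specific k values.

    Starting from the constant-k optimum (all three coordinates equal),
    each sweep maximizes the log-likelihood over one coordinate's grid with
    the others held at their current optima, iterating to a fixed point
    (at most ``max_sweeps`` sweeps).  ``full_grid`` evaluates the complete
    3-D product grid and is only feasible for coarse grids.

    ``profile_curves_`` holds, per behavior, the final-pass log-likelihood
    curve with the other two coordinates at their optima — the curves the
    constant-vs-behavior-dependent model comparison inspects.
    """

    def __init__(
        self,
        k_range=(1.0, 200.0),
        n_grid=200,
        start_score=1000.0,
        start_scores=None,
        dialect="normal",
        strategy="profile",
        max_sweeps=10,
    ):
        self.k_range = k_range
        self.n_grid = n_grid
        self.start_score = start_score
        self.start_scores = start_scores
        self.dialect = dialect
        self.strategy = strategy
        self.max_sweeps = max_sweeps

    def fit(self, records: pd.DataFrame, y=None):
        if len(records) == 0:
            raise ValidationError("cannot optimize k on an empty sequence")
        ks = _k_grid(self.k_range, self.n_grid)
        individuals, w, l, b = _prepare(records)
        start = _start_vector(individuals, self.start_score, self.start_scores)
        present = set(records["behavior"])
        absent = [bb for bb in BEHAVIORS if bb not in present]
        if absent:
            warnings.warn(
                f"behaviors {absent} absent from data; their k stays at the "
                "initialization value",
                stacklevel=2,
            )
        if self.strategy == "full_grid":
            return self._fit_full_grid(records, ks, w, l, b, start)
        if self.strategy != "profile":
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")

        const = ConstantKMLE(
            k_range=self.k_range,
            n_grid=self.n_grid,
            start_score=self.start_score,
            start_scores=self.start_scores,
            dialect=self.dialect,
        ).fit(records)
        current = np.full(3, const.best_k_)
        current_ll = const.max_loglik_
        n_eval = const.n_evaluations_
        curves: dict[str, pd.DataFrame] = {}
        for _ in range(self.max_sweeps):
            improved = False
            for ci, beh in enumerate(BEHAVIORS):
                if beh not in present:
                    curves[beh] = pd.DataFrame(
                        {"param": ks, "loglik": np.full(len(ks), current_ll)}
                    )
                    continue
                k_matrix = np.repeat(current[None, :], len(ks), axis=0)
                k_matrix[:, ci] = ks
                ll = fold_sequence(w, l, b, k_matrix, start, self.dialect)
                n_eval += len(ks)
                curves[beh] = pd.DataFrame({"param": ks, "loglik": ll})
                best = int(np.argmax(ll))
                if ll[best] > current_ll + 1e-12:
                    current = k_matrix[best].copy()
                    current_ll = float(ll[best])
                    improved = True
            if not improved:
                break
        self._finalize(records, current, current_ll, curves, n_eval)
        return self

    def _fit_full_grid(self, records, ks, w, l, b, start):
        if len(ks) ** 3 > 2_000_000:
            raise ConfigurationError(
                "full_grid over this resolution is infeasible; use strategy='profile'"
            )
        grid = np.array(np.meshgrid(ks, ks, ks, indexing="ij")).reshape(3, -1).T
        ll = fold_sequence(w, l, b, grid, start, self.dialect)
        best = int(np.argmax(ll))
        curves = {
            beh: pd.DataFrame({"param": ks, "loglik": np.full(len(ks), np.nan)})
            for beh in BEHAVIORS
        }
        self._finalize(records, grid[best], float(ll[best]), curves, len(grid))
        return self

    def _finalize(self, records, kvec, loglik, curves, n_eval):
        self.best_k_ = {beh: float(kvec[i]) for i, beh in enumerate(BEHAVIORS)}
        self.max_loglik_ = float(loglik)
        self.profile_curves_ = curves
        self.n_evaluations_ = int(n_eval)
        grid_rows = []
        for beh, cur in curves.items():
            cur = cur.assign(behavior=beh)
            grid_rows.append(cur)
        self.result_ = OptimizationResult(
            mode="per_behavior_k",
            best_params=dict(self.best_k_),
            max_loglik=self.max_loglik_,
            evaluation_grid=pd.concat(grid_rows, ignore_index=True),
            n_evaluations=self.n_evaluations_,
            dialect=self.dialect,
            n_events=len(records),
            n_params=3,
        )


class StartValueMLE(BaseEstimator):
    """Randomized maximum-likelihood search over starting scores.

    Draws ``n_draws`` start vectors i.i.d. uniform on 1000 ± ``spread`` per
    individual, recentres each to mean 1000 (the sequence likelihood only
    depends on score differences) and keeps the vector with the largest
    winner-sequence log-likelihood under the supplied k.  The all-equal
    baseline (every start at 1000) is always evaluated alongside and is
    reported as ``baseline_loglik_``.
    """

    def __init__(
        self,
        k=100.0,
        n_draws=2000,
        spread=200.0,
        center=1000.0,
        dialect="normal",
        random_state=None,
    ):
        self.k = k
        self.n_draws = n_draws
        self.spread = spread
        self.center = center
        self.dialect = dialect
        self.random_state = random_state

    def fit(self, records: pd.DataFrame, y=None):
        if len(records) == 0:
            raise ValidationError("cannot optimize starts on an empty sequence")
        if self.n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")
        if not self.spread > 0:
            raise ConfigurationError("spread must be > 0")
        individuals, w, l, b = _prepare(records)
        n_ind = len(individuals)
        rng = np.random.default_rng(self.random_state)
        draws = rng.uniform(
            self.center - self.spread,
            self.center + self.spread,
            size=(int(self.n_draws), n_ind),
        )
        draws += self.center - draws.mean(axis=1, keepdims=True)
        baseline = np.full((1, n_ind), float(self.center))
        starts = np.vstack([baseline, draws])
        ll = fold_sequence(w, l, b, k_vector(self.k), starts, self.dialect)
        self.baseline_loglik_ = float(ll[0])
        best = int(np.argmax(ll))
        self.best_starts_ = {
            ind: float(starts[best, i]) for i, ind in enumerate(individuals)
        }
        self.max_loglik_ = float(ll[best])
        self.n_evaluations_ = len(starts)
        grid = pd.DataFrame(starts, columns=individuals)
        grid["loglik"] = ll
        self.result_ = OptimizationResult(
            mode="start_values",
            best_params=dict(self.best_starts_),
            max_loglik=self.max_loglik_,
            evaluation_grid=grid,
            n_evaluations=self.n_evaluations_,
            seed=self.random_state if isinstance(self.random_state, int) else None,
            dialect=self.dialect,
            n_events=len(records),
            n_params=n_ind,
            baseline_loglik=self.baseline_loglik_,
        )
        return self


# ---------------------------------------------------------------- wrappers
def optimize_constant_k(
    records, start_score=1000.0, start_scores=None, k_range=(1.0, 200.0), n_grid=200, dialect="normal"
) -> OptimizationResult:
    return ConstantKMLE(
        k_range=k_range,
        n_grid=n_grid,
        start_score=start_score,
        start_scores=start_scores,
        dialect=dialect,
    ).fit(records).result_


def optimize_per_behavior_k(
    records,
    start_score=1000.0,
    start_scores=None,
    k_range=(1.0, 200.0),
    n_grid=200,
    dialect="normal",
    strategy="profile",
) -> OptimizationResult:
    return PerBehaviorKMLE(
        k_range=k_range,
        n_grid=n_grid,
        start_score=start_score,
        start_scores=start_scores,
        dialect=dialect,
        strategy=strategy,
    ).fit(records).result_


def optimize_start_values(
    records, k=100.0, n_draws=2000, spread=200.0, seed=None, dialect="normal"
) -> OptimizationResult:
    return StartValueMLE(
        k=k, n_draws=n_draws, spread=spread, dialect=dialect, random_state=seed
    ).fit(records).result_


def compare_models(results, threshold: float = 2.0) -> pd.DataFrame:
    """Tabulate competing optimizations of the *same* sequence.

    Returns one row per result with its parameter count, maximum
    log-likelihood and the log-likelihood deficit to the best model;
    ``most_parsimonious`` flags the model with the fewest parameters among
    those within ``threshold`` log units of the best.
    """
    results = list(results)
    if not results:
        raise ValidationError("no results to compare")
    n_events = {r.n_events for r in results}
    dialects = {r.dialect for r in results}
    if len(n_events) > 1 or len(dialects) > 1:
        raise ValidationError(
            "results were not computed on the same records/dialect: "
            f"n_events={sorted(n_events)}, dialects={sorted(dialects)}"
        )
    best_ll = max(r.max_loglik for r in results)
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.mode,
                "n_params": r.n_params,
                "max_loglik": r.max_loglik,
                "delta_loglik": best_ll - r.max_loglik,
            }
        )
    table = pd.DataFrame(rows)
    within = table["delta_loglik"] < threshold
    flag = np.zeros(len(table), dtype=bool)
    if within.any():
        flag[table.loc[within, "n_params"].idxmin()] = True
    table["most_parsimonious"] = flag
    return table
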
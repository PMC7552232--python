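"""Low-level numerics for sequential Elo rating.

All public modules funnel through the two functions here:

``win_probability``
    the expectation function mapping a rating difference to the probability
    that the higher-rated contestant wins, in either of the two dialects in
    common use (normal-CDF as in the EloRating lineage, or the classic
    base-10 logistic of chess);

``fold_sequence``
    a single pass over a chronological winner/loser sequence that updates a
    whole *batch* of rating states at once.  The batch axis is what makes
    grid searches over k and start-value sampling cheap: evaluating 200 k
    values or 2000 start vectors costs one pass over the events either way.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .errors import ConfigurationError

#: Canonical behavior order used for per-behavior k vectors.
BEHAVIORS: tuple[str, ...] = ("HB", "M", "TB")

DIALECTS: tuple[str, ...] = ("normal", "logistic")

# The normal dialect takes the rating difference on a scale where one
# "class interval" is 200 rating points; the difference of two independent
# performances then has standard deviation 200 * sqrt(2).
_NORMAL_SCALE = 200.0 * np.sqrt(2.0)


def win_probability(diff, dialect: str = "normal"):
    """Probability that the contestant ahead by ``diff`` rating points wins.

    Parameters
    ----------
    diff : array-like
        Rating difference (a − b); any shape.
    dialect : {"normal", "logistic"}
        ``normal``:  Phi(diff / (200 * sqrt(2)))
        ``logistic``: 1 / (1 + 10**(−diff/400))

    Both dialects are strictly increasing in ``diff`` and give exactly 0.5
    at zero difference.
    """
    d = np.asarray(diff, dtype=float)
    if dialect == "normal":
        out = ndtr(d / _NORMAL_SCALE)
    elif dialect == "logistic":
        out = 1.0 / (1.0 + 10.0 ** (-d / 400.0))
    else:
        raise ConfigurationError(
            f"unknown expectation dialect {dialect!r}; expected one of {DIALECTS}"
        )
    if np.ndim(diff) == 0:
        return float(out)
    return out


def behavior_codes(behaviors) -> np.ndarray:
    """Map behavior labels to integer codes in the canonical HB/M/TB order."""
    lookup = {b: i for i, b in enumerate(BEHAVIORS)}
    try:
        return np.array([lookup[b] for b in behaviors], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - guarded upstream by io checks
        raise ConfigurationError(f"unknown behavior code {exc.args[0]!r}") from exc


def k_vector(k) -> np.ndarray:
    """Normalize a k specification to a length-3 vector in BEHAVIORS order.

    ``k`` may be a positive scalar (constant-k model) or a mapping with keys
    HB, M, TB (per-behavior model).
    """
    if np.isscalar(k):
        kf = float(k)
        if not np.isfinite(kf) or kf <= 0:
            raise ConfigurationError(f"k must be positive and finite, got {k!r}")
        return np.full(3, kf)
    try:
        vec = np.array([float(k[b]) for b in BEHAVIORS])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(
            f"per-behavior k must provide keys {BEHAVIORS}, got {k!r}"
        ) from exc
    if not np.all(np.isfinite(vec)) or np.any(vec <= 0):
        raise ConfigurationError(f"per-behavior k values must be positive, got {k!r}")
    return vec


def fold_sequence(
    winner_idx: np.ndarray,
    loser_idx: np.ndarray,
    behavior_idx: np.ndarray,
    k_matrix: np.ndarray,
    start_scores: np.ndarray,
    dialect: str = "normal",
    return_scores: bool = False,
):
    """Fold the Elo update over an event sequence for a batch of states.

    Parameters
    ----------
    winner_idx, loser_idx : int arrays, shape (n_events,)
        Indices into the individual axis.
    behavior_idx : int array, shape (n_events,)
        Codes into BEHAVIORS, selecting the k used for each event.
    k_matrix : shape (batch, 3) or (3,)
        Per-behavior update constants for each batch member.
    start_scores : shape (batch, n_individuals) or (n_individuals,)
        Starting scores for each batch member.
    dialect : expectation dialect.
    return_scores : also return the final score state.

    Returns
    -------
    loglik : shape (batch,) — sum over events of ln P(realized winner).
    scores : shape (batch, n_individuals), only if ``return_scores``.
    """
    k_matrix = np.atleast_2d(np.asarray(k_matrix, dtype=float))
    start = np.asarray(start_scores, dtype=float)
    if start.ndim == 1:
        start = start[None, :]
    batch = max(k_matrix.shape[0], start.shape[0])
    scores = np.broadcast_to(start, (batch, start.shape[1])).copy()
    if k_matrix.shape[0] == 1 and batch > 1:
        k_matrix = np.broadcast_to(k_matrix, (batch, 3))
    rows = np.arange(batch)
    loglik = np.zeros(batch)
    for w, l, b in zip(winner_idx, loser_idx, behavior_idx):
        p = win_probability(scores[:, w] - scores[:, l], dialect)
        loglik += np.log(p)
        delta = k_matrix[rows, b] * (1.0 - p)
        scores[:, w] += delta
        scores[:, l] -= delta
    if return_scores:
        return loglik, scores
    return loglik


def dense_rank_desc(values: np.ndarray) -> np.ndarray:
    """Dense ranks, 1 = largest; tied values share the rank of their block."""
    v = np.asarray(values, dtype=float)
    uniq = np.unique(v)  # ascending
    return (uniq.size - np.searchsorted(uniq, v)).astype(np.intp)
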
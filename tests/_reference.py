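"""Independent plain-loop reference implementations used as test oracles.

Deliberately naive: dict-based state, one event at a time, math-module
special functions only.  Shares no code with the package internals.
"""

import math


def ref_win_probability(sa, sb, dialect="normal"):
    d = sa - sb
    if dialect == "normal":
        return 0.5 * (1.0 + math.erf((d / (200.0 * math.sqrt(2.0))) / math.sqrt(2.0)))
    return 1.0 / (1.0 + 10.0 ** (-d / 400.0))


def ref_trajectory(events, k, start=1000.0, dialect="normal"):
    """events: iterable of (winner, loser, behavior); k: scalar or dict.

    Returns (per-event list of (pre_w, pre_l, post_w, post_l, p_exp), final
    score dict, total log-likelihood).
    """
    scores = {}
    log = []
    loglik = 0.0
    for w, l, b in events:
        scores.setdefault(w, start)
        scores.setdefault(l, start)
        p = ref_win_probability(scores[w], scores[l], dialect)
        kk = k if isinstance(k, (int, float)) else k[b]
        delta = kk * (1.0 - p)
        log.append((scores[w], scores[l], scores[w] + delta, scores[l] - delta, p))
        scores[w] += delta
        scores[l] -= delta
        loglik += math.log(p)
    return log, scores, loglik


def ref_stability(day_scores, weights_day="first"):
    """Slow stability index on a list of per-day score lists.

    Enumerates day pairs and individuals explicitly; dense ranks computed by
    counting distinct larger values.
    """

    def dense_ranks(vals):
        return [len({v for v in vals if v > x}) + 1 for x in vals]

    observed = 0.0
    maximal = 0.0
    changes = 0
    for t in range(len(day_scores) - 1):
        a, b = day_scores[t], day_scores[t + 1]
        ra, rb = dense_ranks(a), dense_ranks(b)
        lo, hi = min(a), max(a)
        n_ranks = max(ra)
        for i in range(len(a)):
            w = 1.0 if hi == lo else (a[i] - lo) / (hi - lo)
            observed += w * abs(rb[i] - ra[i])
            maximal += w * abs(n_ranks + 1 - 2 * ra[i])
            if rb[i] != ra[i]:
                changes += 1
    if maximal == 0:
        return 1.0, changes
    return 1.0 - observed / maximal, changes
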
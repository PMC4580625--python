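"""Independent brute-force oracles used to check the package's statistics.

Everything here is written from definitions (enumeration, direct formulas),
deliberately not sharing code paths with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_r(x, y):
    """Pearson correlation straight from the covariance definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def km_curve(times, events):
    """Product-limit estimator computed by direct accumulation.

    Returns (event_times, survival_probabilities) after each distinct event
    time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
    return out_t, out_s


def logrank_chi2(times, events, in_group1):
    """Two-group log-rank chi-square by direct O-E / variance accumulation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def harrell_c(scores, times, events):
    """Harrell's C by exhaustive enumeration of comparable pairs.

    Higher score = higher predicted risk.  A pair is comparable when the
    smaller observed time carries an event; score ties count 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    assert len(np.unique(times)) == len(times), "oracle assumes distinct times"
    num = den = 0.0
    n = len(scores)
    for i, j in itertools.combinations(range(n), 2):
        ti, tj = times[i], times[j]
        first, second = (i, j) if ti < tj else (j, i)
        if not events[first]:
            continue  # earlier time censored: not comparable
        den += 1
        if scores[first] > scores[second]:
            num += 1
        elif scores[first] == scores[second]:
            num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def hypergeom_upper_tail(k, universe_size, n_successes, n_draws):
    """P(X >= k) by summing exact hypergeometric point masses."""
    total = 0.0
    for kk in range(k, min(n_successes, n_draws) + 1):
        total += (math.comb(n_successes, kk)
                  * math.comb(universe_size - n_successes, n_draws - kk)
                  / math.comb(universe_size, n_draws))
    return min(total, 1.0)


def hypergeom_by_enumeration(module, annotation, universe):
    """P(|draw ∩ annotation| >= observed) over all equally likely draws of
    |module| genes from the universe (feasible for |universe| <= 12)."""
    universe = sorted(universe)
    module = set(module) & set(universe)
    annotation = set(annotation) & set(universe)
    observed = len(module & annotation)
    hits = total = 0
    for draw in itertools.combinations(universe, len(module)):
        total += 1
        if len(set(draw) & annotation) >= observed:
            hits += 1
    return hits / total


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def ranksum_exact_p(group1, group2):
    """Two-sided rank-sum p by enumerating all rank assignments (no ties)."""
    pooled = np.concatenate([group1, group2]).astype(float)
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = pooled.argsort().argsort() + 1
    n1 = len(group1)
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        w = sum(ranks[i] for i in combo)
        if abs(w - mean) >= abs(observed - mean) - 1e-12:
            hits += 1
    return hits / total
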
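"""Independent reference implementations used only to cross-check the
package: brute-force AUC, DeLong's paired AUC test, a point-table PESI
tabulation, a textbook two-group log-rank statistic and a hand-rolled
product-limit estimator.  Deliberately written in a different style
(explicit loops, no shared code) from the implementations they check."""

import math

import numpy as np


def brute_force_auc(scores, died):
    """Pairwise concordance count: concordant + half ties over all
    (non-survivor, survivor) pairs."""
    pos = [s for s, d in zip(scores, died) if d]
    neg = [s for s, d in zip(scores, died) if not d]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def _midranks(values):
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def delong_paired_test(scores_a, scores_b, died):
    """DeLong, DeLong & Clarke-Pearson test for two correlated AUCs.

    Returns (auc_a, auc_b, z, two-sided p).
    """
    died = np.asarray(died, dtype=bool)
    m = int(died.sum())
    n = int((~died).sum())
    thetas = []
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k, raw in enumerate((scores_a, scores_b)):
        x = np.asarray(raw, dtype=float)
        pos, neg = x[died], x[~died]
        combined = np.concatenate([pos, neg])
        rank_all = _midranks(combined)
        rank_pos = _midranks(pos)
        rank_neg = _midranks(neg)
        theta = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        thetas.append(theta)
        v10[k] = (rank_all[:m] - rank_pos) / n
        v01[k] = 1.0 - (rank_all[m:] - rank_neg) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = s10 / m + s01 / n
    delta = thetas[0] - thetas[1]
    denom = var[0, 0] + var[1, 1] - 2.0 * var[0, 1]
    if denom <= 0:
        return thetas[0], thetas[1], 0.0, 1.0
    z = delta / math.sqrt(denom)
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return thetas[0], thetas[1], z, p


# Independent PESI tabulation: points looked up from a flat table keyed by
# attribute name, triggered flags computed with explicit comparisons.
_PESI_POINT_TABLE = {
    "male": 10,
    "heart_failure": 10,
    "chronic_lung": 10,
    "tachycardia": 20,
    "tachypnea": 20,
    "hypothermia": 20,
    "hypoxemia": 20,
    "cancer": 30,
    "hypotension": 30,
    "ams": 60,
}


def pesi_tabulate(age, male, heart_failure, chronic_lung, cancer, ams,
                  heart_rate, sbp, temperature, resp_rate, sao2):
    triggered = {
        "male": male,
        "heart_failure": heart_failure,
        "chronic_lung": chronic_lung,
        "tachycardia": heart_rate >= 110,
        "tachypnea": resp_rate >= 30,
        "hypothermia": temperature < 36.0,
        "hypoxemia": sao2 < 90,
        "cancer": cancer,
        "hypotension": sbp < 100,
        "ams": ams,
    }
    total = int(age)
    for key, points in _PESI_POINT_TABLE.items():
        if triggered[key]:
            total += points
    return total


def logrank_two_group(times_a, events_a, times_b, events_b):
    """Textbook two-group log-rank chi-square: sum over distinct event
    times of (O - E) with the hypergeometric variance."""
    times_a = list(map(float, times_a))
    times_b = list(map(float, times_b))
    event_times = sorted(
        {t for t, e in zip(times_a + times_b, list(events_a) + list(events_b)) if e}
    )
    o_minus_e = 0.0
    variance = 0.0
    for t in event_times:
        n1 = sum(1 for u in times_a if u >= t)
        n2 = sum(1 for u in times_b if u >= t)
        d1 = sum(1 for u, e in zip(times_a, events_a) if e and u == t)
        d2 = sum(1 for u, e in zip(times_b, events_b) if e and u == t)
        n = n1 + n2
        d = d1 + d2
        if n < 1:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            variance += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0
    return o_minus_e**2 / variance


def product_limit(times, events):
    """Hand-rolled Kaplan-Meier: returns {event_time: S(t)}."""
    pairs = sorted(zip(times, events))
    survival = 1.0
    out = {}
    distinct = sorted({t for t, e in pairs if e})
    for t in distinct:
        at_risk = sum(1 for u, _ in pairs if u >= t)
        deaths = sum(1 for u, e in pairs if e and u == t)
        survival *= 1.0 - deaths / at_risk
        out[t] = survival
    return out
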
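"""Independent reference implementations used only by the test suite.

These deliberately re-derive results by the most transparent route possible
(single-pass loops, exact rational enumeration) and share no code with the
package internals they check.
"""

from fractions import Fraction
from math import comb

import numpy as np


def schmitt_trigger_events(values, times, threshold, arm_level, refractory_s):
    """Brute-force single-pass threshold-crossing beat finder.

    An event is the first sample at or above ``threshold`` after the signal
    has been at or below ``arm_level``; events closer than the refractory
    period to the previous accepted event are suppressed and the trigger must
    re-arm either way.
    """
    events = []
    ready = False
    last = None
    for value, t in zip(values, times):
        if ready and value >= threshold:
            if last is None or (t - last) >= refractory_s:
                events.append(t)
                last = t
            ready = False
        if value <= arm_level:
            ready = True
    return events


def default_detection_levels(values, hysteresis_frac=0.10):
    """Re-derive the adaptive threshold/arm level from first principles."""
    p10, p90 = np.percentile(np.asarray(values, dtype=float), [10.0, 90.0])
    threshold = 0.5 * (p10 + p90)
    return threshold, threshold - hysteresis_frac * (p90 - p10)


def fisher_two_sided_enumeration(table):
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    All tables with the observed margins are enumerated in exact rational
    arithmetic; the p-value is the sum of probabilities of tables whose point
    probability does not exceed the observed one.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = sum(
        (p for x in range(max(0, c1 - r2), min(r1, c1) + 1)
         if (p := prob(x)) <= p_obs),
        Fraction(0),
    )
    return float(total)


def hypergeometric_table_probabilities(r1, r2, c1):
    """Probabilities of every table with the given margins (exact, as floats)."""
    n = r1 + r2
    denom = comb(n, c1)
    return [
        float(Fraction(comb(r1, x) * comb(r2, c1 - x), denom))
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    ]


def match_events(detected, truth, tol_s=0.05):
    """Greedy one-to-one matching of detected events to ground truth.

    Returns (true_positives, false_positives, false_negatives).
    """
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(truth.size, dtype=bool)
    tp = fp = 0
    for t in np.asarray(detected, dtype=float):
        if truth.size:
            candidates = np.flatnonzero(~used & (np.abs(truth - t) <= tol_s))
        else:
            candidates = np.empty(0, dtype=int)
        if candidates.size:
            used[candidates[np.argmin(np.abs(truth[candidates] - t))]] = True
            tp += 1
        else:
            fp += 1
    return tp, fp, int(np.count_nonzero(~used))
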
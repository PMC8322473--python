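"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations: exact rational hypergeometric
enumeration for the one-sided Fisher test, a per-event-time
observed-minus-expected accumulation for the log-rank statistic, and the
empirical survival function.  They share no code with the package paths
they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X hypergeometric with the table's margins.

    Table [[a, b], [c, d]]; 'greater' = first row enriched for the first
    column.  Exact rational arithmetic, converted to float at the end.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = comb(n, c1)
    total = Fraction(0)
    for k in range(a, hi + 1):
        total += Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    if not lo <= a <= hi:
        return 1.0 if a <= lo else 0.0
    return float(total)


def logrank_oracle(
    times_a, events_a, times_b, events_b
) -> float:
    """Mantel-Cox chi-square accumulated naively per distinct event time."""
    subjects = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in subjects if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        # risk set: everyone still under observation at t (ties: events
        # and censorings at t are both still at risk at t)
        n1 = sum(1 for tt, _, g in subjects if g == 0 and tt >= t)
        n2 = sum(1 for tt, _, g in subjects if g == 1 and tt >= t)
        n = n1 + n2
        d1 = sum(1 for tt, e, g in subjects if g == 0 and e and tt == t)
        d2 = sum(1 for tt, e, g in subjects if g == 1 and e and tt == t)
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def empirical_survival(times, t: float) -> float:
    """S(t) with no censoring: fraction of subjects surviving past t."""
    times = list(times)
    return sum(1 for x in times if x > t) / len(times)
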
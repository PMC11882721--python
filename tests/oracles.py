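"""Independent brute-force oracles used to freeze expected test values."""

import math


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive margin-preserving enumeration.

    Uses exact integer arithmetic: the probability of a table with
    top-left cell x is proportional to C(r1, x) * C(r2, c1 - x), so the
    two-sided p sums every table whose weight is at most the observed one
    (1e-7 relative tolerance on the comparison, handled as a rational
    inequality so no floating-point rounding enters).
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    total = math.comb(r1 + r2, c1)
    acc = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        if w * 10**7 <= w_obs * (10**7 + 1):
            acc += w
    return acc / total


def pearson_chi2(table) -> float:
    """Uncorrected Pearson chi-squared statistic on a 2x2 table."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    stat = 0.0
    for obs, r, col in ((a, r1, c1), (b, r1, c2), (c, r2, c1), (d, r2, c2)):
        e = r * col / n
        stat += (obs - e) ** 2 / e
    return stat
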
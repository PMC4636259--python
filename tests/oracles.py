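"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the code paths they validate: exact rational
arithmetic for Fisher, hand-rolled midranks for the rank-sum score, bisection
on the binomial tail equations for Clopper-Pearson.
"""

from __future__ import annotations

import math
from fractions import Fraction


def midranks(values):
    """Midranks by explicit sort-and-average (no scipy)."""
    idx = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[idx[j + 1]] == values[idx[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[idx[k]] = avg
        i = j + 1
    return ranks


def rank_sum_oracle(values, flagged_idx, tail="right"):
    """Normalized rank sum over flagged indices; left tail ranks -values."""
    obs = [(-v if tail == "left" else v) for v in values if v == v]  # drop NaN
    kept = [i for i, v in enumerate(values) if v == v]
    ranks = midranks(obs)
    pos = {orig: r for orig, r in zip(kept, ranks)}
    if not flagged_idx:
        return 0.0
    return sum(pos[i] for i in flagged_idx) / len(obs)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration (math.comb)."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    denom = math.comb(n, col1)
    probs = {
        x: Fraction(math.comb(row1, x) * math.comb(n - row1, col1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def _binom_cdf(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1))


def clopper_pearson_bisect(x, n, level=0.95, tol=1e-9):
    """CP interval by bisection on the binomial tail equations."""
    alpha = 1 - level

    def solve(f, lo, hi):
        # f monotone increasing with f(lo) < 0 < f(hi)
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else solve(
        lambda p: (1 - _binom_cdf(x - 1, n, p)) - alpha / 2, 0.0, 1.0
    )
    upper = 1.0 if x == n else solve(
        lambda p: alpha / 2 - _binom_cdf(x, n, p), 0.0, 1.0
    )
    return lower, upper


def spearman_no_ties_oracle(x, y):
    """1 - 6 sum d^2 / (n (n^2-1)); valid only without ties."""
    n = len(x)
    rx = midranks(list(x))
    ry = midranks(list(y))
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1 - 6 * d2 / (n * (n**2 - 1))
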
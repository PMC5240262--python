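"""Independent brute-force reference implementations used only by tests.

These deliberately avoid numpy/scipy and the package's own code paths so
they can serve as oracles for the weighted sum, the OLS fit and the Kendall
tau-b statistic.
"""

from __future__ import annotations

import math


def weighted_sum(scores: dict[str, int], weights: dict[str, float]) -> float:
    """Elementwise sum-of-products over criterion ids, plain Python."""
    total = 0.0
    for cid in weights:
        total += weights[cid] * scores[cid]
    return total


def ols_normal_equations(points) -> tuple[float, float, float]:
    """Simple OLS with intercept via the closed-form normal equations.

    Returns (slope, intercept, r_squared).
    """
    n = len(points)
    xs = [float(p[0]) for p in points]
    ys = [float(p[1]) for p in points]
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    syy = sum((y - ybar) ** 2 for y in ys)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
    r2 = 1.0 - ss_res / syy if syy > 0 else float("nan")
    return slope, intercept, r2


def kendall_tau_b(ranks_a, ranks_b) -> float:
    """Tie-corrected Kendall tau by exhaustive pair enumeration."""
    n = len(ranks_a)
    concordant = discordant = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da = ranks_a[i] - ranks_a[j]
            db = ranks_b[i] - ranks_b[j]
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif (da > 0) == (db > 0):
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    n1 = sum(_tie_pairs(ranks_a))
    n2 = sum(_tie_pairs(ranks_b))
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def _tie_pairs(ranks):
    counts: dict = {}
    for r in ranks:
        counts[r] = counts.get(r, 0) + 1
    return (c * (c - 1) // 2 for c in counts.values())
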
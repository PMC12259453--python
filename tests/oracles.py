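"""Independent brute-force oracles used to cross-check the package's
statistics.  Everything here is deliberately naive — enumeration, rational
arithmetic, direct textbook formulas — and shares no code with the
implementation paths it checks."""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def kendall_tau_b_pairs(x, y) -> float:
    """Kendall tau-b by exhaustive pair counting with tie corrections."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom if denom else float("nan")


def _tie_term(v) -> float:
    counts: dict[float, int] = {}
    for val in v:
        counts[val] = counts.get(val, 0) + 1
    return sum(c * (c - 1) // 2 for c in counts.values())


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Number of tie-free arrangements for each Mann-Whitney U value."""
    if n1 == 0 or n2 == 0:
        return (1,)
    shifted = _u_counts(n1 - 1, n2)  # largest value from sample 1: U += n2
    kept = _u_counts(n1, n2 - 1)
    size = n1 * n2 + 1
    out = [0] * size
    for u, c in enumerate(shifted):
        out[u + n2] += c
    for u, c in enumerate(kept):
        out[u] += c
    return tuple(out)


def mann_whitney_exact_p(x, y) -> tuple[float, float]:
    """(U of x, exact two-sided p) for tie-free samples, by DP enumeration."""
    x = list(map(float, x))
    y = list(map(float, y))
    u = sum((xi > yj) for xi in x for yj in y)
    dist = np.array(_u_counts(len(x), len(y)), dtype=float)
    dist /= dist.sum()
    p_le = dist[: u + 1].sum()
    p_ge = dist[u:].sum()
    return float(u), float(min(1.0, 2.0 * min(p_le, p_ge)))


def _hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(X = a) for the 2x2 table with row sums r1, r2 and first column c1."""
    return Fraction(math.comb(r1, a) * math.comb(r2, c1 - a),
                    math.comb(r1 + r2, c1))


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (exact rationals).

    Sums point probabilities that do not exceed the observed one, with the
    customary 1 + 1e-7 relative tolerance for floating-point agreement.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = _hypergeom_pmf(a, r1, r2, c1)
    tol = Fraction(10_000_001, 10_000_000)
    total = sum(_hypergeom_pmf(k, r1, r2, c1)
                for k in range(lo, hi + 1)
                if _hypergeom_pmf(k, r1, r2, c1) <= p_obs * tol)
    return float(total)


def fisher_or_cmle(table, tol: float = 1e-10) -> float:
    """Conditional-MLE odds ratio by bisection on the noncentral
    hypergeometric mean equation."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0
    support = list(range(lo, hi + 1))
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in support]

    def mean(psi: float) -> float:
        terms = [w * psi ** (k - lo) for w, k in zip(weights, support)]
        total = sum(terms)
        return sum(k * t for k, t in zip(support, terms)) / total

    left, right = 1e-12, 1e12
    for _ in range(200):
        mid = math.sqrt(left * right)
        if mean(mid) < a:
            left = mid
        else:
            right = mid
        if right / left < 1 + tol:
            break
    return math.sqrt(left * right)


def quantile_type7(values, q: float) -> float:
    """Linear interpolation between order statistics (R type 7)."""
    v = sorted(float(x) for x in values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def winsorize_clamp(values, tail: float) -> list[float]:
    """Order-statistic clamping oracle for Winsorization."""
    lo = quantile_type7(values, tail)
    hi = quantile_type7(values, 1.0 - tail)
    return [min(max(x, lo), hi) for x in values]


def welch_statistic(x, y) -> tuple[float, float]:
    """Textbook Welch t statistic and Welch–Satterthwaite df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    return t, df


def pearson_direct(x, y) -> float:
    """Pearson r straight from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
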
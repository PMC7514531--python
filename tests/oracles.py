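"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the defining formulas with plain
nested loops (or, for EMD, the plainest possible sifting loop), sharing no
code with the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import CubicSpline


# ---------------------------------------------------------------- entropy

def apen_brute(x, m: int, r: float) -> float:
    """Approximate entropy by direct template counting (self-matches in)."""
    x = list(map(float, x))
    l = len(x)

    def phi(mm):
        n = l - mm + 1
        templates = [x[i:i + mm] for i in range(n)]
        total = 0.0
        for a in templates:
            c = 0
            for b in templates:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    c += 1
            total += math.log(c / n)
        return total / n

    return phi(m) - phi(m + 1)


def sampen_brute(x, m: int, r: float) -> float:
    """Sample entropy: pooled off-diagonal counts over l-m templates."""
    x = list(map(float, x))
    l = len(x)
    n = l - m

    def count(mm):
        templates = [x[i:i + mm] for i in range(n)]
        c = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if max(abs(u - v) for u, v in
                       zip(templates[i], templates[j])) <= r:
                    c += 1
        return c

    B = count(m)
    A = count(m + 1)
    if A == 0 or B == 0:
        return float("inf")
    return -math.log(A / B)


def fuzzen_brute(x, m: int, r: float, power: float = 2.0) -> float:
    """Fuzzy entropy: baseline-removed templates, exponential membership."""
    x = list(map(float, x))
    l = len(x)
    n = l - m

    def phi(mm):
        templates = []
        for i in range(n):
            t = x[i:i + mm]
            mu = sum(t) / mm
            templates.append([v - mu for v in t])
        total = 0.0
        for i in range(n):
            s = 0.0
            for j in range(n):
                if i == j:
                    continue
                d = max(abs(u - v) for u, v in
                        zip(templates[i], templates[j]))
                s += math.exp(-((d / r) ** power))
            total += s / (n - 1)
        return total / n

    return math.log(phi(m)) - math.log(phi(m + 1))


def _pattern(window) -> tuple:
    """Ordinal pattern; ties broken by order of occurrence."""
    return tuple(sorted(range(len(window)), key=lambda i: (window[i], i)))


def peen_brute(x, m: int, tau: int = 1) -> float:
    x = list(map(float, x))
    counts: dict = {}
    n = len(x) - (m - 1) * tau
    for i in range(n):
        p = _pattern([x[i + k * tau] for k in range(m)])
        counts[p] = counts.get(p, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p)
    return h


def wpeen_brute(x, m: int, tau: int = 1) -> float:
    x = list(map(float, x))
    n = len(x) - (m - 1) * tau
    weights: dict = {}
    total = 0.0
    for i in range(n):
        w = [x[i + k * tau] for k in range(m)]
        mu = sum(w) / m
        var = sum((v - mu) ** 2 for v in w) / m
        p = _pattern(w)
        weights[p] = weights.get(p, 0.0) + var
        total += var
    if total == 0:
        return 0.0
    h = 0.0
    for wv in weights.values():
        if wv > 0:
            p = wv / total
            h -= p * math.log(p)
    return h


def incren_brute(x, m: int, phi: int = 2) -> float:
    x = list(map(float, x))
    v = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    mu = sum(v) / len(v)
    sd = math.sqrt(sum((u - mu) ** 2 for u in v) / len(v))
    symbols = []
    for u in v:
        s = (u > 0) - (u < 0)
        q = 0 if sd == 0 else min(phi, math.floor(abs(u) * phi / sd))
        symbols.append((s, q))
    counts: dict = {}
    n = len(symbols) - m + 1
    for i in range(n):
        w = tuple(symbols[i:i + m])
        counts[w] = counts.get(w, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p)
    return h


# -------------------------------------------------------------------- GLR

def glr_naive(buffer, theta: int, order: int = 1) -> float:
    """Corrected GLR at one split via two-pass segment statistics."""
    x = list(map(float, buffer))
    q = len(x)

    def biased_var(seg):
        mu = sum(seg) / len(seg)
        return sum((v - mu) ** 2 for v in seg) / len(seg)

    s0q = biased_var(x)
    if s0q == 0:
        return 0.0
    s0t = biased_var(x[:theta])
    stq = biased_var(x[theta:])
    if s0t == 0 or stq == 0:
        return float("inf")
    g = theta * math.log(s0q / s0t) + (q - theta) * math.log(s0q / stq)
    c = 1.0 + (11.0 / 12.0) * (1.0 / theta + 1.0 / (q - theta) - 1.0 / q)
    if order >= 2:
        c += 1.0 / theta**2 + 1.0 / (q - theta) ** 2 - 1.0 / q**2
    return g / c


def glr_scan_naive(buffer, order: int = 1):
    """(g_max, theta_hat) by recomputing every split from scratch."""
    q = len(buffer)
    best, best_t = -math.inf, None
    for t in range(2, q - 1):
        g = glr_naive(buffer, t, order)
        if g > best:
            best, best_t = g, t
    return best, best_t


# -------------------------------------------------------------------- EMD

def reference_imf1(x) -> np.ndarray:
    """First IMF by the plainest textbook sifting (no boundary handling).

    Envelopes are not-a-knot cubic splines through interior extrema with
    the series endpoints appended as knots; ten fixed sifting passes.
    Edge behavior differs from any boundary-extended method, so
    comparisons should use interior samples only.
    """
    h = np.asarray(x, dtype=float).copy()
    n = len(h)
    t = np.arange(n)
    for _ in range(10):
        dx = np.diff(h)
        maxima = [i for i in range(1, n - 1)
                  if h[i] > h[i - 1] and h[i] > h[i + 1]]
        minima = [i for i in range(1, n - 1)
                  if h[i] < h[i - 1] and h[i] < h[i + 1]]
        if len(maxima) < 2 or len(minima) < 2:
            break
        up = CubicSpline([0] + maxima + [n - 1],
                         np.concatenate([[h[0]], h[maxima], [h[-1]]]))
        lo = CubicSpline([0] + minima + [n - 1],
                         np.concatenate([[h[0]], h[minima], [h[-1]]]))
        h = h - 0.5 * (up(t) + lo(t))
    return h
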
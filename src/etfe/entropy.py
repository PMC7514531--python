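"""Entropy estimators that coarse-grain a signal segment into one number.

Six estimators are provided.  ApEn, SampEn and FuzzEn count near-matching
embedded subsequences under the Chebyshev distance (SampEn drops
self-matches; FuzzEn replaces the hard match by an exponential membership
on baseline-removed templates).  PeEn and WPeEn take the Shannon entropy
of ordinal (rank-order) patterns, the weighted variant scaling each
pattern occurrence by the variance of its embedding vector.  IncrEn
encodes first differences as (sign, quantized magnitude) symbols and takes
the Shannon entropy of fixed-length symbol words.

All logarithms are natural.  The similarity radius ``r`` is, by default, a
multiple of the standard deviation of the scored segment itself, which
makes ApEn/SampEn/FuzzEn scale-invariant; all six estimators are
translation-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "EntropyConfig",
    "embed",
    "apen",
    "sampen",
    "fuzzen",
    "peen",
    "wpeen",
    "incren",
    "entropy_value",
    "METHODS",
]

#: sentinel returned by SampEn/FuzzEn when no template pair matches
NO_MATCH = float("inf")


@dataclass(frozen=True)
class EntropyConfig:
    """Estimator choice and its parameters.

    gamma    embedding (template/pattern/word) length
    r        similarity radius; multiple of the segment std when
             ``r_mode == "std"``, absolute otherwise (apen/sampen/fuzzen)
    tau      embedding delay (peen/wpeen)
    phi      quantization resolution of increment magnitudes (incren)
    fuzz_power  exponent of the fuzzy membership function (fuzzen)
    """

    method: str = "apen"
    gamma: int = 3
    r: float = 0.2
    tau: int = 1
    phi: int = 2
    fuzz_power: float = 2.0
    r_mode: str = "std"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown entropy method {self.method!r}; "
                             f"choose from {sorted(METHODS)}")
        if self.gamma < 2:
            raise ValueError(f"gamma must be >= 2, got {self.gamma}")
        if self.method in ("apen", "sampen", "fuzzen") and self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.phi < 1:
            raise ValueError(f"phi must be >= 1, got {self.phi}")
        if self.r_mode not in ("std", "abs"):
            raise ValueError(f"r_mode must be 'std' or 'abs', got {self.r_mode!r}")

    @classmethod
    def default_for(cls, method: str) -> "EntropyConfig":
        """Standard parameterization per estimator (gamma=4, tau=1 for the
        ordinal estimators; gamma=3 elsewhere; r=0.2 std; phi=2)."""
        if method in ("peen", "wpeen"):
            return cls(method=method, gamma=4, tau=1)
        return cls(method=method, gamma=3)


def _as_series(x, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    if len(x) < min_len:
        raise ValueError(f"series must have at least {min_len} samples, got {len(x)}")
    return x


def embed(series, gamma: int, tau: int = 1) -> np.ndarray:
    """Delay-embedding matrix: row i = series[i : i+(gamma-1)*tau+1 : tau].

    Rows appear in source order; there are ``l - (gamma-1)*tau`` of them.
    """
    span = (gamma - 1) * tau + 1
    x = _as_series(series, span)
    return sliding_window_view(x, span)[:, ::tau]


def _radius(x: np.ndarray, cfg: EntropyConfig) -> float:
    if cfg.r_mode == "abs":
        return cfg.r
    return cfg.r * float(np.std(x))


def _cheb(E: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distances between embedding rows."""
    return np.max(np.abs(E[:, None, :] - E[None, :, :]), axis=2)


def apen(series, cfg: EntropyConfig) -> float:
    """Approximate entropy: phi^gamma(r) - phi^(gamma+1)(r).

    Template matches use d <= r with self-matches included, so every
    count is positive and the log is always defined.  A zero-variance
    segment (with r given as a std multiple) returns 0.
    """
    m = cfg.gamma
    x = _as_series(series, m + 2)
    r = _radius(x, cfg)
    if r == 0:
        return 0.0

    def phi(mm: int) -> float:
        E = embed(x, mm, 1)
        C = np.mean(_cheb(E) <= r, axis=1)
        return float(np.mean(np.log(C)))

    return phi(m) - phi(m + 1)


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Pooled off-diagonal match counts at lengths m (B) and m+1 (A).

    Both lengths use the same l - m templates (the standard convention),
    so the ratio A/B is a conditional match probability.
    """
    n_t = len(x) - m
    Em = embed(x, m, 1)[:n_t]
    Em1 = embed(x, m + 1, 1)
    dB = _cheb(Em)
    dA = _cheb(Em1)
    np.fill_diagonal(dB, np.inf)
    np.fill_diagonal(dA, np.inf)
    return int(np.count_nonzero(dA <= r)), int(np.count_nonzero(dB <= r))


def sampen(series, cfg: EntropyConfig) -> float:
    """Sample entropy: -ln(A/B) with self-matches excluded."""
    m = cfg.gamma
    x = _as_series(series, m + 2)
    r = _radius(x, cfg)
    if r == 0:
        return 0.0
    A, B = _match_counts(x, m, r)
    if A == 0 or B == 0:
        warnings.warn("sampen: no template matches; returning no-match sentinel",
                      stacklevel=2)
        return NO_MATCH
    return float(-np.log(A / B))


def fuzzen(series, cfg: EntropyConfig) -> float:
    """Fuzzy entropy: ln Phi^gamma - ln Phi^(gamma+1).

    Templates are baseline-removed (own mean subtracted); similarity is
    exp(-(d/r)^fuzz_power); self-matches are excluded.
    """
    m = cfg.gamma
    x = _as_series(series, m + 2)
    r = _radius(x, cfg)
    if r == 0:
        return 0.0

    def phi(mm: int, n_t: int) -> float:
        E = embed(x, mm, 1)[:n_t]
        E = E - E.mean(axis=1, keepdims=True)
        sim = np.exp(-((_cheb(E) / r) ** cfg.fuzz_power))
        np.fill_diagonal(sim, 0.0)
        return float(np.sum(sim) / (n_t * (n_t - 1)))

    n_t = len(x) - m
    pm, pm1 = phi(m, n_t), phi(m + 1, n_t)
    if pm == 0 or pm1 == 0:
        warnings.warn("fuzzen: vanishing similarity; returning no-match sentinel",
                      stacklevel=2)
        return NO_MATCH
    return float(np.log(pm) - np.log(pm1))


def _ordinal_patterns(E: np.ndarray) -> np.ndarray:
    """Map embedding rows to ordinal patterns; ties rank earlier indices lower."""
    return np.argsort(E, axis=1, kind="stable")


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def peen(series, cfg: EntropyConfig) -> float:
    """Permutation entropy: Shannon entropy of the ordinal-pattern frequencies."""
    E = embed(series, cfg.gamma, cfg.tau)
    pats = _ordinal_patterns(E)
    _, counts = np.unique(pats, axis=0, return_counts=True)
    return _shannon(counts / counts.sum())


def wpeen(series, cfg: EntropyConfig) -> float:
    """Weighted permutation entropy.

    Each pattern occurrence is weighted by the variance of its embedding
    vector, so large-amplitude structure dominates the distribution.  An
    all-constant series (all weights zero) returns 0.
    """
    E = embed(series, cfg.gamma, cfg.tau)
    w = E.var(axis=1)
    total = w.sum()
    if total == 0:
        return 0.0
    pats = _ordinal_patterns(E)
    _, inverse = np.unique(pats, axis=0, return_inverse=True)
    wsum = np.bincount(inverse, weights=w)
    return _shannon(wsum / total)


def incren(series, cfg: EntropyConfig) -> float:
    """Increment entropy.

    First differences v_k are encoded as (sign, q) with
    q = min(phi, floor(|v_k| * phi / std(v))); the result is the Shannon
    entropy of the distribution of length-gamma words of these symbols.
    """
    m = cfg.gamma
    x = _as_series(series, m + 1)
    v = np.diff(x)
    s = np.sign(v).astype(int)
    sd = float(np.std(v))
    if sd == 0:
        q = np.zeros(len(v), dtype=int)
    else:
        q = np.minimum(cfg.phi, np.floor(np.abs(v) * cfg.phi / sd)).astype(int)
    symbols = s * (cfg.phi + 1) + np.where(s == 0, 0, q)  # unique int per (s, q)
    words = sliding_window_view(symbols, m)
    _, counts = np.unique(words, axis=0, return_counts=True)
    return _shannon(counts / counts.sum())


METHODS = {
    "apen": apen,
    "sampen": sampen,
    "fuzzen": fuzzen,
    "peen": peen,
    "wpeen": wpeen,
    "incren": incren,
}


def entropy_value(series, cfg: EntropyConfig) -> float:
    """Dispatch to the estimator named in ``cfg.method``."""
    return METHODS[cfg.method](series, cfg)
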
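"""Empirical mode decomposition with extrema-symmetric boundary extension.

EMD splits a signal into intrinsic mode functions (IMFs) by iteratively
subtracting the mean of cubic-spline envelopes fitted through the local
maxima and minima ("sifting").  Envelopes computed on a finite window
diverge near its ends; here the window is first extended on both sides by
mirroring about the extremum nearest each end (or about the endpoint itself
when the endpoint is more extreme), which anchors the splines outside the
observed support.  All returned components live on the original support:
padding is stripped, so the IMFs plus the residual sum exactly back to the
input.

Indices are 0-based throughout; windows are half-open intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "ExtremaIndex",
    "ExtendedWindow",
    "ImfSet",
    "find_extrema",
    "extend_boundaries",
    "sift_imf",
    "decompose",
]

#: default sifting-iteration cap per IMF
MAX_SIFT_ITER = 50
#: standard-deviation sifting stop criterion (Huang's SD)
SD_TOLERANCE = 0.2
#: mean-envelope magnitude considered "zero", relative to the IMF amplitude
MEAN_ENVELOPE_TOLERANCE = 0.05


@dataclass(frozen=True)
class ExtremaIndex:
    """Interior local extrema of a window, plateaus collapsed.

    Runs of equal values are treated as a single sample located at the
    run's first index, so maxima and minima strictly alternate.
    """

    maxima_positions: np.ndarray
    minima_positions: np.ndarray
    maxima_values: np.ndarray
    minima_values: np.ndarray

    @property
    def n_maxima(self) -> int:
        return len(self.maxima_positions)

    @property
    def n_minima(self) -> int:
        return len(self.minima_positions)


@dataclass(frozen=True)
class ExtendedWindow:
    """A window with mirror padding; stripping the pads recovers the input."""

    values: np.ndarray
    left_pad: int
    right_pad: int
    d: int

    def strip(self) -> np.ndarray:
        n = len(self.values) - self.left_pad - self.right_pad
        return self.values[self.left_pad:self.left_pad + n]


@dataclass
class ImfSet:
    """Ordered IMFs plus the final residual for one window."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_counts: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for h in self.imfs:
            out += h
        return out


def _as_window(x, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"window must be 1-D, got shape {x.shape}")
    if len(x) < min_len:
        raise ValueError(f"window must have at least {min_len} samples, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    return x


def find_extrema(window) -> ExtremaIndex:
    """Locate all strict interior extrema of ``window``.

    Equal-valued plateaus collapse to one extremum at the plateau's first
    sample.  Endpoints are never reported as extrema.
    """
    x = _as_window(window, 3)
    # collapse runs of equal values: keep the first sample of each run
    keep = np.empty(len(x), dtype=bool)
    keep[0] = True
    keep[1:] = x[1:] != x[:-1]
    starts = np.flatnonzero(keep)
    vals = x[starts]
    if len(vals) < 3:
        empty = np.empty(0, dtype=int)
        return ExtremaIndex(empty, empty.copy(), np.empty(0), np.empty(0))
    mid = vals[1:-1]
    is_max = (mid > vals[:-2]) & (mid > vals[2:])
    is_min = (mid < vals[:-2]) & (mid < vals[2:])
    maxima = starts[1:-1][is_max]
    minima = starts[1:-1][is_min]
    return ExtremaIndex(maxima, minima, x[maxima], x[minima])


def _mirror_left(x: np.ndarray, center: int, d: int) -> np.ndarray:
    """Mirror ``x`` about index ``center``; return samples landing left of 0."""
    n = len(x)
    src = np.arange(center + 1, min(center + d, n - 1) + 1)
    dest = 2 * center - src  # descending
    keep = dest < 0
    # ascending destination order
    return x[src[keep]][::-1]


def _mirror_right(x: np.ndarray, center: int, d: int) -> np.ndarray:
    n = len(x)
    src = np.arange(max(center - d, 0), center)
    dest = 2 * center - src  # descending
    keep = dest > n - 1
    return x[src[keep]][::-1]


def extend_boundaries(window, d: int) -> ExtendedWindow:
    """Extend ``window`` by up to ``d`` mirrored samples on each side.

    The mirror centre on each side is the extremum nearest that end when
    the endpoint lies inside the envelope span (e.g. first extremum is a
    maximum and the endpoint exceeds the first minimum); otherwise the
    endpoint itself is the centre.  Mirrored samples whose reflected index
    falls inside the original support would overwrite observed data and
    are dropped, so the pads can be shorter than ``d``.
    """
    if d <= 0:
        raise ValueError(f"extension length d must be positive, got {d}")
    x = _as_window(window, 3)
    n = len(x)
    ex = find_extrema(x)

    # --- left side ---
    left_center = 0
    if ex.n_maxima and ex.n_minima:
        if ex.maxima_positions[0] < ex.minima_positions[0]:
            # first extremum is a maximum; mirror about it unless the
            # endpoint dips below the first minimum
            if x[0] > ex.minima_values[0]:
                left_center = int(ex.maxima_positions[0])
        else:
            if x[0] < ex.maxima_values[0]:
                left_center = int(ex.minima_positions[0])
    pad_left = _mirror_left(x, left_center, d)

    # --- right side ---
    right_center = n - 1
    if ex.n_maxima and ex.n_minima:
        if ex.maxima_positions[-1] > ex.minima_positions[-1]:
            if x[-1] > ex.minima_values[-1]:
                right_center = int(ex.maxima_positions[-1])
        else:
            if x[-1] < ex.maxima_values[-1]:
                right_center = int(ex.minima_positions[-1])
    pad_right = _mirror_right(x, right_center, d)

    values = np.concatenate([pad_left, x, pad_right])
    return ExtendedWindow(values, len(pad_left), len(pad_right), d)


def _envelope(positions: np.ndarray, values: np.ndarray, n_ext: int,
              fallback: tuple[float, float]) -> np.ndarray:
    """Envelope through knots, evaluated on 0..n_ext-1.

    Cubic spline (natural end conditions) needs >= 2 knots; with fewer the
    envelope degenerates to an endpoint-anchored line.
    """
    t = np.arange(n_ext)
    if len(positions) >= 2:
        cs = CubicSpline(positions, values, bc_type="natural")
        return cs(t)
    # endpoint-anchored line through whatever knots exist
    xs = np.concatenate([[0.0], positions.astype(float), [float(n_ext - 1)]])
    ys = np.concatenate([[fallback[0]], values, [fallback[1]]])
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    xs, uniq = np.unique(xs, return_index=True)
    return np.interp(t, xs, ys[uniq])


def _mean_envelope(h: np.ndarray, d: int) -> np.ndarray | None:
    """Mean of the upper/lower envelopes over the original support.

    Returns None when ``h`` has no interior extrema (residual-like).
    """
    ex = find_extrema(h)
    if ex.n_maxima == 0 or ex.n_minima == 0:
        return None
    ext = extend_boundaries(h, d)
    exx = find_extrema(ext.values)
    n_ext = len(ext.values)
    upper = _envelope(exx.maxima_positions, exx.maxima_values, n_ext,
                      (ext.values[0], ext.values[-1]))
    lower = _envelope(exx.minima_positions, exx.minima_values, n_ext,
                      (ext.values[0], ext.values[-1]))
    p = 0.5 * (upper + lower)
    n = len(h)
    return p[ext.left_pad:ext.left_pad + n]


def _zero_crossings(h: np.ndarray) -> int:
    s = np.sign(h)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _imf_conditions(h: np.ndarray, p: np.ndarray) -> bool:
    ex = find_extrema(h)
    n_extrema = ex.n_maxima + ex.n_minima
    if abs(n_extrema - _zero_crossings(h)) > 1:
        return False
    amp = np.max(np.abs(h))
    if amp == 0:
        return True
    return np.max(np.abs(p)) <= MEAN_ENVELOPE_TOLERANCE * amp


def sift_imf(signal, d: int | None = None, max_iter: int = MAX_SIFT_ITER,
             sd_tol: float = SD_TOLERANCE) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Extract one IMF from ``signal`` by envelope-mean sifting.

    Returns ``(imf, residual, iterations, converged)`` with
    ``imf + residual == signal`` exactly.  A signal without interior
    extrema is declared residual (zero IMF, 0 iterations).  Sifting stops
    when Huang's SD criterion drops below ``sd_tol`` or both IMF
    conditions (extrema/zero-crossing counts within 1, mean envelope
    negligible) hold; hitting ``max_iter`` returns the current candidate
    with ``converged=False`` and a warning.
    """
    x = _as_window(signal, 3)
    if d is None:
        d = max(1, int(np.ceil(len(x) / 10)))

    h = x.copy()
    for it in range(1, max_iter + 1):
        p = _mean_envelope(h, d)
        if p is None:
            if it == 1:
                # no extrema at all: monotone / residual-like input
                return np.zeros_like(x), x.copy(), 0, True
            break
        h_new = h - p
        denom = np.sum(h * h)
        sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_tol or _imf_conditions(h, p):
            return h, x - h, it, True
    if it >= max_iter:
        warnings.warn(f"sifting hit the {max_iter}-iteration cap", stacklevel=2)
        return h, x - h, it, False
    return h, x - h, it, True


def decompose(window, max_imfs: int | None = None, d: int | None = None,
              max_iter: int = MAX_SIFT_ITER, sd_tol: float = SD_TOLERANCE) -> ImfSet:
    """Decompose ``window`` into IMFs and a residual.

    IMFs are peeled off successive residuals until ``max_imfs`` is reached
    or the residual is monotone / has fewer than 2 interior extrema.  The
    components are returned on the original support and sum back to the
    input exactly (floating addition aside).
    """
    x = _as_window(window, 8)
    if d is None:
        d = max(1, int(np.ceil(len(x) / 10)))
    if max_imfs is not None and max_imfs < 1:
        raise ValueError(f"max_imfs must be >= 1, got {max_imfs}")

    imfs: list[np.ndarray] = []
    counts: list[int] = []
    flags: list[bool] = []
    residual = x.copy()
    while max_imfs is None or len(imfs) < max_imfs:
        ex = find_extrema(residual)
        if ex.n_maxima + ex.n_minima < 2:
            break
        imf, residual, n_it, ok = sift_imf(residual, d=d, max_iter=max_iter,
                                           sd_tol=sd_tol)
        if n_it == 0:
            break
        imfs.append(imf)
        counts.append(n_it)
        flags.append(ok)
    return ImfSet(imfs, residual, counts, flags)
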
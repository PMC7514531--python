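"""GLR control chart for shifts in mean and/or variance of a stream.

The chart models the monitored stream as i.i.d. Gaussian and compares, at
every time q, the likelihood of one homogeneous segment against the best
split into two segments with their own means and variances.  With segment
dispersion S_{i,j} (biased variance of x[i+1..j]) the statistic at split
theta is

    G_{theta,q} = [theta ln(S_{0,q}/S_{0,theta})
                   + (q-theta) ln(S_{0,q}/S_{theta,q})] / C,

where C is a Bartlett-type correction that brings the null expectation of
the statistic to its chi-squared degrees of freedom (2).  The breakpoint
search is restricted to the H most recent observations (Willsky-Jones
window), which bounds both memory and per-step cost.

Control limits delta_q come from a Monte-Carlo calibration targeting a
constant false-alarm hazard of 1/ARL on null streams: per-q conditional
survivor quantiles while the buffer fills, then a single stationary tail
threshold chosen so the mean residual run length of surviving null streams
equals the target ARL.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GlrState",
    "GlrResult",
    "ThresholdTable",
    "bartlett_factor",
    "glr_statistic",
    "update_state",
    "max_glr",
    "calibrate_thresholds",
    "step_monitor",
    "null_run_lengths",
]

#: minimum buffer length before the breakpoint scan is defined
MIN_SCAN_LEN = 5


@dataclass
class GlrState:
    """Recursive sufficient statistics plus the H most recent observations.

    ``w`` is the running sum W_q and ``p`` the running sum of squared
    deviations from the running mean P_{0,q}; both are updated in O(1)
    per observation.  The buffer holds at most H values, so state size is
    bounded regardless of stream length.
    """

    H: int = 200
    startup_n: int = 0
    q: int = 0
    w: float = 0.0
    p: float = 0.0
    buffer: deque = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.H < MIN_SCAN_LEN:
            raise ValueError(f"H must be >= {MIN_SCAN_LEN}, got {self.H}")
        if self.buffer is None:
            self.buffer = deque(maxlen=self.H)

    @property
    def buffer_start(self) -> int:
        """Stream index of the oldest buffered observation."""
        return self.q - len(self.buffer)


@dataclass(frozen=True)
class GlrResult:
    """Outcome of one breakpoint scan."""

    g_max: float
    theta_hat: int  # stream index of the maximizing split
    per_theta: np.ndarray | None = None


def bartlett_factor(theta: int, q: int, order: int = 1) -> float:
    """Correction divisor making E[G] ~ 2 under the null.

    ``order=1`` is the first-order factor
    1 + (11/12)(1/theta + 1/(q-theta) - 1/q); ``order=2`` adds the
    second-order terms 1/theta^2 + 1/(q-theta)^2 - 1/q^2.
    """
    c = 1.0 + (11.0 / 12.0) * (1.0 / theta + 1.0 / (q - theta) - 1.0 / q)
    if order >= 2:
        c += 1.0 / theta**2 + 1.0 / (q - theta) ** 2 - 1.0 / q**2
    return c


def glr_statistic(buffer, theta: int, correction_order: int = 1) -> float:
    """Bartlett-corrected GLR statistic for a split at ``theta``.

    ``theta`` must leave at least two observations on each side.  A
    buffer with zero overall dispersion returns 0; zero dispersion inside
    a segment (with overall dispersion positive) returns +inf, a certain
    change.
    """
    x = np.asarray(buffer, dtype=float)
    q = len(x)
    if not 2 <= theta <= q - 2:
        raise ValueError(f"theta must lie in [2, {q - 2}], got {theta}")
    v0 = float(x.var())
    if v0 == 0.0:
        return 0.0
    v1 = float(x[:theta].var())
    v2 = float(x[theta:].var())
    if v1 == 0.0 or v2 == 0.0:
        return float("inf")
    g = theta * np.log(v0 / v1) + (q - theta) * np.log(v0 / v2)
    return float(g) / bartlett_factor(theta, q, correction_order)


def update_state(state: GlrState, x_new: float) -> GlrState:
    """Fold one observation into the recursive statistics (in place).

    W_{q+1} = W_q + x;  P_{0,q+1} = P_{0,q} + q (x - W_q/q)^2 / (q+1).
    The oldest buffered value is evicted when the buffer is full.
    """
    if not np.isfinite(x_new):
        raise ValueError(f"observation must be finite, got {x_new}")
    q = state.q
    if q > 0:
        state.p += q * (x_new - state.w / q) ** 2 / (q + 1)
    state.w += x_new
    state.q = q + 1
    state.buffer.append(float(x_new))
    return state


def _scan(Y: np.ndarray, correction_order: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrected G over all admissible splits for each row of ``Y``.

    Segment means and variances come from prefix sums (the fast update
    forms), O(n) per row.  Returns (g_max, theta_rel, per_theta).
    """
    R, n = Y.shape
    Y = Y - Y.mean(axis=1, keepdims=True)  # conditioning; variances unchanged
    cs = np.concatenate([np.zeros((R, 1)), np.cumsum(Y, axis=1)], axis=1)
    css = np.concatenate([np.zeros((R, 1)), np.cumsum(Y * Y, axis=1)], axis=1)
    th = np.arange(2, n - 1)
    n1 = th.astype(float)
    n2 = n - n1
    m1 = cs[:, th] / n1
    m2 = (cs[:, [n]] - cs[:, th]) / n2
    v1 = css[:, th] / n1 - m1**2
    v2 = (css[:, [n]] - css[:, th]) / n2 - m2**2
    v0 = css[:, [n]] / n - (cs[:, [n]] / n) ** 2
    v1 = np.maximum(v1, 0.0)
    v2 = np.maximum(v2, 0.0)
    c = np.array([bartlett_factor(int(t), n, correction_order) for t in th])
    with np.errstate(divide="ignore", invalid="ignore"):
        G = (n1 * np.log(v0 / v1) + n2 * np.log(v0 / v2)) / c
    G = np.where(v0 <= 0.0, 0.0, G)          # constant buffer: no evidence
    G = np.where((v0 > 0.0) & ((v1 == 0.0) | (v2 == 0.0)), np.inf, G)
    idx = np.argmax(G, axis=1)               # first max: ties toward smallest theta
    return G[np.arange(R), idx], th[idx], G


def max_glr(state_or_buffer, correction_order: int = 1,
            keep_per_theta: bool = False) -> GlrResult:
    """Scan all admissible breakpoints in the buffer for the largest G.

    Accepts a :class:`GlrState` (theta_hat is then a stream index) or a
    plain sequence (theta_hat is an index into it).  Ties break toward
    the smallest split.
    """
    if isinstance(state_or_buffer, GlrState):
        buf = np.asarray(state_or_buffer.buffer, dtype=float)
        offset = state_or_buffer.buffer_start
    else:
        buf = np.asarray(state_or_buffer, dtype=float)
        offset = 0
    if len(buf) < MIN_SCAN_LEN:
        raise ValueError(f"buffer must hold at least {MIN_SCAN_LEN} observations, "
                         f"got {len(buf)}")
    g, th, G = _scan(buf[None, :], correction_order)
    return GlrResult(float(g[0]), int(offset + th[0]),
                     G[0] if keep_per_theta else None)


@dataclass
class ThresholdTable:
    """ARL-calibrated control-limit schedule delta_q.

    ``deltas[i]`` is the limit at stream length ``q0 + i``; lengths below
    ``q0`` are never tested (limit +inf) and lengths beyond the table use
    the stationary ``delta_tail``.
    """

    arl: float
    H: int
    q0: int
    deltas: np.ndarray
    delta_tail: float
    reps: int
    seed: int
    correction_order: int = 1
    version: int = 1

    def delta(self, q: int) -> float:
        if q < self.q0:
            return float("inf")
        i = q - self.q0
        if i < len(self.deltas):
            return float(self.deltas[i])
        return self.delta_tail

    def delta_array(self, qs: np.ndarray) -> np.ndarray:
        out = np.full(len(qs), self.delta_tail)
        out[qs < self.q0] = np.inf
        inside = (qs >= self.q0) & (qs < self.q0 + len(self.deltas))
        out[inside] = self.deltas[qs[inside] - self.q0]
        return out

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "arl": self.arl,
            "H": self.H,
            "q0": self.q0,
            "deltas": [float(v) for v in self.deltas],
            "delta_tail": self.delta_tail,
            "reps": self.reps,
            "seed": self.seed,
            "correction_order": self.correction_order,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdTable":
        d = json.loads(text)
        return cls(arl=d["arl"], H=d["H"], q0=d["q0"],
                   deltas=np.asarray(d["deltas"], dtype=float),
                   delta_tail=d["delta_tail"], reps=d["reps"], seed=d["seed"],
                   correction_order=d.get("correction_order", 1),
                   version=d.get("version", 1))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ThresholdTable":
        return cls.from_json(Path(path).read_text())


def calibrate_thresholds(arl: float, H: int = 200, q_max: int | None = None,
                         reps: int = 5000, seed: int = 0, startup: int = 10,
                         correction_order: int = 1,
                         tail_horizon: int | None = None) -> ThresholdTable:
    """Monte-Carlo control limits for a target average run length.

    Null N(0,1) streams are monitored exactly as the chart would monitor
    them.  For q in [q0, q_max] the limit is the (1 - 1/ARL) quantile of
    G_max among streams that have not yet alarmed, so the per-q false
    alarm hazard is 1/ARL.  Beyond q_max the window is full and the scan
    distribution is stationary; a constant tail limit is found by
    bisection so that the mean residual run length among surviving
    streams matches the ARL.
    """
    if arl < 10:
        raise ValueError(f"arl must be >= 10, got {arl}")
    min_reps = int(max(200, 2 * arl))
    if reps < min_reps:
        raise ValueError(f"reps={reps} too small to estimate the 1-1/arl "
                         f"quantile; need >= {min_reps}")
    q0 = max(int(startup) + 1, MIN_SCAN_LEN)
    if q_max is None:
        q_max = H + q0
    if tail_horizon is None:
        tail_horizon = int(3 * arl)

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((reps, q_max + tail_horizon))
    alive = np.ones(reps, dtype=bool)
    deltas = np.empty(q_max - q0 + 1)
    prob = 1.0 - 1.0 / arl
    for q in range(q0, q_max + 1):
        a = max(0, q - H)
        g, _, _ = _scan(X[alive, a:q], correction_order)
        if np.count_nonzero(alive) < max(100, int(arl / 2)):
            raise ValueError("too few surviving null streams for quantile "
                             "estimation; increase reps")
        d = float(np.quantile(g, prob))
        deltas[q - q0] = d
        idx = np.flatnonzero(alive)
        alive[idx[g > d]] = False

    # stationary tail: bisect a constant limit on the survivors' G paths
    surv = X[alive]
    n_surv = len(surv)
    G2 = np.empty((n_surv, tail_horizon))
    for j in range(tail_horizon):
        q = q_max + 1 + j
        a = q - H
        G2[:, j], _, _ = _scan(surv[:, a:q], correction_order)

    def mean_rl(delta: float) -> float:
        hit = G2 > delta
        first = np.where(hit.any(axis=1), hit.argmax(axis=1) + 1, tail_horizon)
        return float(first.mean())

    # truncated-exponential target: E[min(RL, horizon)] at hazard 1/arl
    target = arl * (1.0 - np.exp(-tail_horizon / arl))
    lo, hi = 0.0, float(np.max(G2[np.isfinite(G2)])) + 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_rl(mid) < target:
            lo = mid
        else:
            hi = mid
    delta_tail = 0.5 * (lo + hi)

    return ThresholdTable(arl=float(arl), H=H, q0=q0, deltas=deltas,
                          delta_tail=delta_tail, reps=reps, seed=seed,
                          correction_order=correction_order)


def step_monitor(state: GlrState, x_new: float, table: ThresholdTable,
                 correction_order: int | None = None
                 ) -> tuple[GlrState, tuple[int, float] | None]:
    """Feed one observation; return ``(state, (theta_hat, g_max) | None)``.

    Testing starts once ``q`` clears the startup count and the buffer
    holds enough observations for a scan.  An alarm does not reset the
    state; that is the caller's policy.
    """
    order = table.correction_order if correction_order is None else correction_order
    state = update_state(state, x_new)
    if state.q <= state.startup_n or len(state.buffer) < MIN_SCAN_LEN:
        return state, None
    res = max_glr(state, order)
    if res.g_max > table.delta(state.q):
        return state, (res.theta_hat, res.g_max)
    return state, None


def null_run_lengths(table: ThresholdTable, n_streams: int, seed: int,
                     max_len: int | None = None) -> np.ndarray:
    """Run length to first (false) alarm on fresh i.i.d. N(0,1) streams.

    Streams that never alarm within ``max_len`` observations are recorded
    at ``max_len`` (with a warning if that happens often).  Vectorized
    across streams; equivalent to stepping :func:`step_monitor` with a
    zero startup.
    """
    if max_len is None:
        max_len = int(12 * table.arl)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_streams, max_len))
    rl = np.full(n_streams, max_len, dtype=int)
    alive = np.ones(n_streams, dtype=bool)
    for q in range(table.q0, max_len + 1):
        a = max(0, q - table.H)
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        g, _, _ = _scan(X[idx, a:q], table.correction_order)
        hit = g > table.delta(q)
        rl[idx[hit]] = q
        alive[idx[hit]] = False
    n_censored = int(np.count_nonzero(alive))
    if n_censored > 0.01 * n_streams:
        warnings.warn(f"{n_censored}/{n_streams} null streams censored at "
                      f"max_len={max_len}", stacklevel=2)
    return rl
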
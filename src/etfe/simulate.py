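"""Synthetic AR drift benchmark and detector scoring.

A benchmark series concatenates several autoregressive "concepts":
x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + w_t with w_t ~ N(0, sigma^2).
Drift is injected by switching the coefficient vector and noise scale at
concept boundaries while the AR history carries across, so transitions
are seamless rather than re-initialized jumps.  The three standard groups
(LINEAR1/2/3) each chain four concepts of 3,000 samples; the noise-scale
column (0.5 ... 3.5) is read as a standard deviation by default.

Detector output is scored with four metrics: mean detection delay, mean
position offset, false-alarm count and miss count.  Each true drift
claims the earliest unclaimed alarm whose estimated change position falls
within ``match_horizon`` samples after it; everything unclaimed is a
false alarm, every unclaimed drift a miss.
"""

from __future__ import annotations

import numpy as np

from dataclasses import dataclass, field

from .detector import DetectorConfig, DriftAlarm, process_stream
from .glr_spc import ThresholdTable

__all__ = [
    "ConceptSpec",
    "BenchmarkSeries",
    "EvalReport",
    "LINEAR1",
    "LINEAR2",
    "LINEAR3",
    "TWO_CONCEPT_DEMO",
    "GROUPS",
    "generate_concept_series",
    "evaluate_alarms",
    "run_benchmark",
]


@dataclass(frozen=True)
class ConceptSpec:
    """One AR concept: coefficients (lag order = len), noise scale, length."""

    coefficients: tuple
    noise_scale: float
    length: int

    def __post_init__(self):
        if len(self.coefficients) < 1:
            raise ValueError("concept needs at least one AR coefficient")
        if self.noise_scale < 0:
            raise ValueError(f"noise_scale must be >= 0, got {self.noise_scale}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class BenchmarkSeries:
    """A generated series with its ground-truth drift positions."""

    values: np.ndarray
    drift_points: tuple
    group: str
    seed: int


@dataclass(frozen=True)
class EvalReport:
    """The four benchmark metrics for one detector run.

    ``detection_delay`` and ``position_offset`` are means over matched
    (true) alarms and NaN when nothing matched.
    """

    detection_delay: float
    position_offset: float
    false_alarms: int
    miss_detections: int
    n_true_drifts: int = 0
    n_alarms: int = 0


def _concepts(rows, length: int = 3000) -> tuple:
    return tuple(ConceptSpec(tuple(a), s, length) for a, s in rows)


#: the three benchmark groups: (coefficients, noise std) per concept
LINEAR1 = _concepts([
    ((0.9, -0.2, 0.8, -0.5), 0.5),
    ((-0.3, 1.4, 0.4, -0.5), 1.5),
    ((1.5, -0.4, -0.3, 0.2), 2.5),
    ((-0.1, 1.4, 0.4, -0.7), 3.5),
])
LINEAR2 = _concepts([
    ((1.1, -0.6, 0.8, -0.5, -0.1, 0.3), 0.5),
    ((-0.1, 1.2, 0.4, 0.3, -0.2, -0.6), 1.5),
    ((1.2, -0.4, -0.3, 0.7, -0.6, 0.4), 2.5),
    ((-0.1, 1.1, 0.5, 0.2, -0.2, -0.5), 3.5),
])
LINEAR3 = _concepts([
    ((0.5, 0.5), 0.5),
    ((1.5, 0.5), 1.5),           # explosive: generation raises
    ((0.9, -0.2, 0.8, -0.5), 2.5),
    ((0.9, 0.8, -0.6, 0.2, -0.5, -0.2, 0.4), 3.5),
])
#: two-concept demonstration stream (2,000 samples each, unit noise)
TWO_CONCEPT_DEMO = _concepts([
    ((1.5, -0.4, -0.3, 0.2), 1.0),
    ((-0.1, 1.2, 0.4, -0.5), 1.0),
], length=2000)

GROUPS = {"linear1": LINEAR1, "linear2": LINEAR2, "linear3": LINEAR3}


def generate_concept_series(specs, seed: int, burn_in: int = 500,
                            noise_as_variance: bool = False,
                            group: str = "custom") -> BenchmarkSeries:
    """Simulate the AR concept chain; history carries across boundaries.

    A ``burn_in`` stretch under the first concept is generated and
    discarded so the series starts free of initialization transients.
    ``noise_as_variance`` reads the noise scales as variances instead of
    standard deviations.  An explosive concept (non-finite values) raises
    a ValueError naming it.
    """
    specs = tuple(specs)
    if not specs:
        raise ValueError("need at least one concept")
    rng = np.random.default_rng(seed)
    p_max = max(len(s.coefficients) for s in specs)
    history = np.zeros(p_max)

    def run(spec: ConceptSpec, n: int, label: str) -> np.ndarray:
        nonlocal history
        a = np.asarray(spec.coefficients)[::-1]  # align with history order
        p = len(a)
        sd = np.sqrt(spec.noise_scale) if noise_as_variance else spec.noise_scale
        w = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        out = np.empty(n)
        h = history[-p:].copy()
        with np.errstate(over="ignore", invalid="ignore"):
            for t in range(n):
                v = float(a @ h) + w[t]
                out[t] = v
                h[:-1] = h[1:]
                h[-1] = v
        if not np.all(np.isfinite(out)):
            raise ValueError(f"AR recursion diverged in {label} "
                             f"(coefficients {spec.coefficients})")
        if n >= p_max:
            history = out[-p_max:].copy()
        else:
            history = np.concatenate([history, out])[-p_max:]
        return out

    if burn_in > 0:
        run(specs[0], burn_in, "burn-in")
    parts = [run(s, s.length, f"concept {i + 1}") for i, s in enumerate(specs)]
    drift_points = tuple(np.cumsum([s.length for s in specs[:-1]]).tolist())
    return BenchmarkSeries(np.concatenate(parts), drift_points, group, seed)


def evaluate_alarms(alarms, truth, match_horizon: int = 1000) -> EvalReport:
    """Score alarms against ground-truth drift indices.

    Alarms must be sorted by detection time.  Each drift (in order)
    claims the earliest unclaimed alarm with change_position in
    [drift, drift + match_horizon); delay = detection_time - drift and
    offset = |change_position - drift| are averaged over claims.
    """
    alarms = list(alarms)
    times = [a.detection_time for a in alarms]
    if times != sorted(times):
        raise ValueError("alarms must be sorted by detection_time")
    truth = sorted(int(v) for v in truth)

    claimed = [False] * len(alarms)
    delays, offsets = [], []
    misses = 0
    for drift in truth:
        hit = None
        for i, a in enumerate(alarms):
            if claimed[i]:
                continue
            if drift <= a.change_position < drift + match_horizon:
                hit = i
                break
        if hit is None:
            misses += 1
        else:
            claimed[hit] = True
            delays.append(alarms[hit].detection_time - drift)
            offsets.append(abs(alarms[hit].change_position - drift))
    false_alarms = claimed.count(False)
    return EvalReport(
        detection_delay=float(np.mean(delays)) if delays else float("nan"),
        position_offset=float(np.mean(offsets)) if offsets else float("nan"),
        false_alarms=false_alarms,
        miss_detections=misses,
        n_true_drifts=len(truth),
        n_alarms=len(alarms),
    )


@dataclass(frozen=True)
class BenchmarkSummary:
    """Mean and standard deviation of each metric across series x runs."""

    mean: EvalReport
    sd: EvalReport
    reports: tuple = field(default=())


def run_benchmark(group: str, n_series: int, n_runs: int,
                  detector_cfg: DetectorConfig, table: ThresholdTable,
                  seed: int, match_horizon: int = 1000,
                  burn_in: int = 500) -> BenchmarkSummary:
    """Generate series, run the detector, aggregate the four metrics.

    Every run of every series is generated fresh from a seed spawned off
    ``seed``, so the n_series x n_runs reports are independent
    replicates.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; choose from {sorted(GROUPS)}")
    specs = GROUPS[group]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(n_series * n_runs)]
    reports = []
    for k in range(n_series * n_runs):
        series = generate_concept_series(specs, seed=child_seeds[k],
                                         burn_in=burn_in, group=group)
        alarms = process_stream(series.values, detector_cfg, table)
        reports.append(evaluate_alarms(alarms, series.drift_points,
                                       match_horizon))

    def agg(fn) -> EvalReport:
        def col(name):
            vals = np.asarray([getattr(r, name) for r in reports], dtype=float)
            vals = vals[np.isfinite(vals)]
            return float(fn(vals)) if len(vals) else float("nan")
        return EvalReport(detection_delay=col("detection_delay"),
                          position_offset=col("position_offset"),
                          false_alarms=col("false_alarms"),
                          miss_detections=col("miss_detections"),
                          n_true_drifts=col("n_true_drifts"),
                          n_alarms=col("n_alarms"))

    return BenchmarkSummary(mean=agg(np.mean),
                            sd=agg(lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0),
                            reports=tuple(reports))
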
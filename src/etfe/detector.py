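"""Sliding-window drift detection: EMD -> IMF entropy -> GLR monitoring.

For every arriving sample (once the raw window has filled, and at the
configured stride) the current window is decomposed, the configured IMF is
coarse-grained to a single entropy value, and that value is fed to a GLR
control chart.  When the chart alarms, the estimated breakpoint in the
entropy stream is mapped back to a raw-stream index and the chart is
restarted from the next observation; the raw window itself persists, so
detection resumes immediately.

The entropy stream produced from overlapping windows is strongly
autocorrelated while the chart's null calibration assumes i.i.d.
observations; in practice this inflates the false-alarm rate relative to
the nominal ARL.  See docs/methods.md for the consequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .emd import decompose
from .entropy import EntropyConfig, entropy_value
from .glr_spc import GlrState, ThresholdTable, step_monitor

__all__ = ["DetectorConfig", "DriftAlarm", "process_stream", "map_alarm_position"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    """Everything the online pipeline needs.

    window_size  raw samples per decomposition window
    stride       raw samples between successive entropy evaluations
    imf_index    which IMF to monitor, 1-based (1 = highest frequency)
    entropy      estimator choice and parameters
    arl          target average run length of the control chart
    startup      observations before testing starts: a fraction of the
                 stream length when < 1 (sized input required), else an
                 absolute raw-sample count
    glr_window   H, the breakpoint-search window of the chart
    max_imfs     IMFs extracted per window (>= imf_index)
    d            boundary-extension length; default ceil(window_size/10)
    """

    window_size: int = 100
    stride: int = 1
    imf_index: int = 1
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    arl: float = 200.0
    startup: float = 0.1
    glr_window: int = 200
    max_imfs: int = 2
    d: int | None = None

    def __post_init__(self):
        if self.window_size < 8:
            raise ValueError(f"window_size must be >= 8, got {self.window_size}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.imf_index < 1:
            raise ValueError(f"imf_index must be >= 1, got {self.imf_index}")
        if self.imf_index > self.max_imfs:
            raise ValueError(f"imf_index={self.imf_index} exceeds "
                             f"max_imfs={self.max_imfs}")
        if self.startup < 0:
            raise ValueError(f"startup must be >= 0, got {self.startup}")

    @property
    def extension_length(self) -> int:
        if self.d is not None:
            return self.d
        return max(1, int(np.ceil(self.window_size / 10)))

    @property
    def stream_label(self) -> str:
        return f"imf{self.imf_index}_{self.entropy.method}"


@dataclass(frozen=True)
class DriftAlarm:
    """One detected drift, with 0-based raw-stream indices."""

    detection_time: int
    change_position: int
    statistic: float
    stream_label: str


def map_alarm_position(theta_hat: int, cfg: DetectorConfig) -> int:
    """Map an entropy-stream index to a raw-stream index.

    The entropy value at step t summarizes the raw window
    [t*stride, t*stride + window_size); the alarm is attributed to the
    window's right edge.
    """
    return theta_hat * cfg.stride + cfg.window_size - 1


def _startup_entropy_count(cfg: DetectorConfig, n_raw: int | None) -> int:
    """Entropy observations produced before the startup gate lifts."""
    if cfg.startup < 1:
        if n_raw is None:
            raise ValueError("fractional startup requires a sized input stream")
        startup_raw = int(cfg.startup * n_raw)
    else:
        startup_raw = int(cfg.startup)
    if startup_raw < cfg.window_size:
        return 0
    return (startup_raw - cfg.window_size) // cfg.stride + 1


def process_stream(stream, cfg: DetectorConfig, table: ThresholdTable,
                   return_trace: bool = False):
    """Run the full pipeline over ``stream``; return the drift alarms.

    ``stream`` may be any iterable of finite reals; a sequence is required
    when ``cfg.startup`` is a fraction.  With ``return_trace=True`` the
    entropy stream (one value per evaluated window) is returned alongside
    the alarms.  A stream shorter than the window yields no alarms and a
    warning.
    """
    try:
        n_raw = len(stream)
    except TypeError:
        n_raw = None
    startup_n = _startup_entropy_count(cfg, n_raw)

    w = cfg.window_size
    window = np.empty(w)
    n_seen = 0
    state = GlrState(H=cfg.glr_window, startup_n=startup_n)
    offset = 0          # entropy-stream index where the current chart began
    t = 0               # global entropy-stream index
    alarms: list[DriftAlarm] = []
    trace: list[float] = []

    for x in stream:
        x = float(x)
        if not np.isfinite(x):
            raise ValueError(f"stream value at raw index {n_seen} is not finite")
        window[:-1] = window[1:]
        window[-1] = x
        n_seen += 1
        if n_seen < w or (n_seen - w) % cfg.stride != 0:
            continue

        imfset = decompose(window, max_imfs=cfg.max_imfs, d=cfg.extension_length)
        if len(imfset) < cfg.imf_index:
            logger.debug("window ending at %d: only %d IMFs, skipping",
                         n_seen - 1, len(imfset))
            t += 1
            continue
        e = entropy_value(imfset.imfs[cfg.imf_index - 1], cfg.entropy)
        if not np.isfinite(e):
            logger.debug("window ending at %d: non-finite entropy, skipping",
                         n_seen - 1)
            t += 1
            continue
        if return_trace:
            trace.append(e)

        state, alarm = step_monitor(state, e, table)
        if alarm is not None:
            theta_hat, g_max = alarm
            change_raw = map_alarm_position(offset + theta_hat, cfg)
            alarms.append(DriftAlarm(detection_time=n_seen - 1,
                                     change_position=change_raw,
                                     statistic=g_max,
                                     stream_label=cfg.stream_label))
            logger.info("drift alarm at raw index %d (change at %d, G=%.3f)",
                        n_seen - 1, change_raw, g_max)
            # restart: fresh chart from the next observation; raw window kept
            state = GlrState(H=cfg.glr_window, startup_n=0)
            offset = t + 1
        t += 1

    if n_seen < w:
        warnings.warn(f"stream of {n_seen} samples is shorter than the "
                      f"window ({w}); no alarms possible", stacklevel=2)
    if return_trace:
        return alarms, np.asarray(trace)
    return alarms
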
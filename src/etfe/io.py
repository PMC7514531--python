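"""CSV stream readers/writers, YAML configuration, provenance records.

The interchange format is deliberately plain: a series is one numeric
column (optional header, optional leading timestamp column which is
ignored for computation); alarms are a four-column CSV.  All indices in
files are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import DriftAlarm
from .entropy import EntropyConfig

__all__ = [
    "read_series",
    "write_series",
    "write_alarms",
    "read_alarms",
    "write_truth",
    "read_truth",
    "load_config",
    "write_provenance",
]

ALARM_COLUMNS = ["detection_time", "change_position", "statistic", "stream_label"]


def read_series(path) -> np.ndarray:
    """Read a univariate series: one value per row, last column numeric.

    A non-numeric header row is skipped; with two columns the first
    (timestamp) is ignored.  Non-numeric cells are reported with their
    1-based row number.
    """
    path = Path(path)
    raw = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise ValueError(f"{path}: empty series file")
    start = 0
    try:
        float(raw[0].split(",")[-1])
    except ValueError:
        start = 1  # header
        if len(raw) == 1:
            raise ValueError(f"{path}: header but no data rows")
    values = np.empty(len(raw) - start)
    for i, ln in enumerate(raw[start:]):
        cell = ln.split(",")[-1].strip()
        try:
            values[i] = float(cell)
        except ValueError:
            raise ValueError(f"{path}: non-numeric value {cell!r} at row "
                             f"{start + i + 1}") from None
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise ValueError(f"{path}: non-finite value at row {start + bad + 1}")
    return values


def write_series(values, path) -> None:
    """One value per row, headerless, full float precision."""
    Path(path).write_text("".join(f"{float(v)!r}\n"
                                  for v in np.asarray(values, float)))


def write_alarms(alarms, path) -> None:
    """Alarm CSV: detection_time,change_position,statistic,stream_label.

    Indices are integers; the statistic keeps enough digits to
    round-trip.
    """
    df = pd.DataFrame(
        [(a.detection_time, a.change_position, a.statistic, a.stream_label)
         for a in alarms],
        columns=ALARM_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_alarms(path) -> list[DriftAlarm]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ALARM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing alarm columns {missing}")
    return [DriftAlarm(detection_time=int(r.detection_time),
                       change_position=int(r.change_position),
                       statistic=float(r.statistic),
                       stream_label=str(r.stream_label))
            for r in df.itertuples(index=False)]


def write_truth(drift_points_by_series: dict, path) -> None:
    """Ground-truth CSV: series_id,drift_index (one row per drift)."""
    rows = [(sid, int(dp)) for sid, dps in drift_points_by_series.items()
            for dp in dps]
    pd.DataFrame(rows, columns=["series_id", "drift_index"]).to_csv(path,
                                                                    index=False)


def read_truth(path) -> dict:
    df = pd.read_csv(path)
    out: dict = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.series_id), []).append(int(r.drift_index))
    return out


#: keys accepted in a YAML run configuration
CONFIG_KEYS = {
    "entropy", "gamma", "r", "tau", "phi", "fuzz_power",
    "window", "stride", "imf", "max_imfs", "d",
    "arl", "startup", "glr_window",
    "thresholds", "seed", "log_level",
    "group", "series", "runs", "horizon", "burn_in",
}


def load_config(path) -> dict:
    """Load a flat YAML key-value config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def entropy_config_from(options: dict) -> EntropyConfig:
    """Build an EntropyConfig from flat CLI/YAML options."""
    method = options.get("entropy", "apen")
    cfg = EntropyConfig.default_for(method)
    overrides = {k: options[k] for k in ("gamma", "r", "tau", "phi", "fuzz_power")
                 if options.get(k) is not None}
    if overrides:
        from dataclasses import replace
        cfg = replace(cfg, **overrides)
    return cfg


def write_provenance(path, command: str, options: dict, seed) -> None:
    """Record what produced an output file, next to it."""
    from . import __version__
    rec = {"tool": "etfe", "version": __version__, "command": command,
           "seed": seed, "options": {k: v for k, v in sorted(options.items())
                                     if not callable(v)}}
    Path(path).write_text(json.dumps(rec, indent=1, default=str))
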
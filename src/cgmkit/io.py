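"""CGM time-series container and CSV round-trip.

The canonical on-disk dialect is a two-column CSV with header
``timestamp,glucose``: ISO-8601 naive local timestamps (second resolution)
and interstitial glucose in mg/dL (0.1 mg/dL resolution).  Values outside
the sensor reporting range [39, 401] mg/dL are clamped on read, mirroring
the LO/HI codes real CGM exports contain.

No module in this package ever imputes missing readings: a gap (consecutive
timestamp difference larger than the nominal interval) simply propagates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: CGM sensor reporting range, mg/dL.  Readings are clamped here, never dropped.
SENSOR_FLOOR = 39.0
SENSOR_CEILING = 401.0

CSV_COLUMNS = ("timestamp", "glucose")
_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True, eq=False)
class GlucoseSeries:
    """Timestamped interstitial glucose readings on a nominal grid.

    Parameters
    ----------
    timestamps
        Strictly increasing naive datetimes, one per reading.
    values
        Glucose in mg/dL, within the sensor range [39, 401].
    nominal_interval
        Nominal sampling interval in minutes (default 5).  Any consecutive
        timestamp difference larger than this is a gap.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    nominal_interval: int = 5

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if len(ts) != len(vals):
            raise ValueError(
                f"timestamps ({len(ts)}) and values ({len(vals)}) differ in length"
            )
        if len(ts) > 1:
            diffs = np.diff(ts.asi8)
            if np.any(diffs <= 0):
                raise ValueError("timestamps must be strictly increasing (no duplicates)")
        if len(vals) and (vals.min() < SENSOR_FLOOR or vals.max() > SENSOR_CEILING):
            raise ValueError(
                f"glucose values must lie in [{SENSOR_FLOOR}, {SENSOR_CEILING}] mg/dL; "
                "clamp before constructing the series"
            )
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be positive")
        vals.flags.writeable = False
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlucoseSeries):
            return NotImplemented
        return (
            self.nominal_interval == other.nominal_interval
            and len(self) == len(other)
            and bool(self.timestamps.equals(other.timestamps))
            and bool(np.array_equal(self.values, other.values))
        )

    def gaps(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Return (last reading before, first reading after) for every gap."""
        if len(self) < 2:
            return []
        diffs = np.diff(self.timestamps.asi8) / 60e9  # minutes
        idx = np.nonzero(diffs > self.nominal_interval)[0]
        return [(self.timestamps[i], self.timestamps[i + 1]) for i in idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "glucose": self.values})


def clamp_values(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Clamp glucose to the sensor range; return (clamped, n_clamped)."""
    values = np.asarray(values, dtype=float)
    n = int(np.count_nonzero((values < SENSOR_FLOOR) | (values > SENSOR_CEILING)))
    return np.clip(values, SENSOR_FLOOR, SENSOR_CEILING), n


def read_cgm_csv(path, nominal_interval: int = 5) -> GlucoseSeries:
    """Read a two-column ``timestamp,glucose`` CSV into a :class:`GlucoseSeries`.

    Rows are sorted by time; duplicate timestamps are rejected; values
    outside the sensor range are clamped with a logged warning.
    """
    df = pd.read_csv(path)
    if list(df.columns) != list(CSV_COLUMNS):
        raise ValueError(
            f"{path}: expected header {','.join(CSV_COLUMNS)!r}, got {list(df.columns)}"
        )
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    vals = pd.to_numeric(df["glucose"]).to_numpy(dtype=float)
    order = np.argsort(ts.to_numpy(), kind="stable")
    ts = pd.DatetimeIndex(ts.to_numpy()[order])
    vals = vals[order]
    if len(ts) > 1 and np.any(np.diff(ts.asi8) == 0):
        raise ValueError(f"{path}: duplicate timestamps after sorting")
    vals, n_clamped = clamp_values(vals)
    if n_clamped:
        logger.warning(
            "%s: clamped %d reading(s) to the sensor range [%g, %g] mg/dL",
            path, n_clamped, SENSOR_FLOOR, SENSOR_CEILING,
        )
    return GlucoseSeries(ts, vals, nominal_interval=nominal_interval)


def write_cgm_csv(series: GlucoseSeries, path) -> None:
    """Write the canonical CSV dialect.  Round-trips through
    :func:`read_cgm_csv` to the second (timestamps) and 0.1 mg/dL (values)."""
    df = series.to_frame()
    df.to_csv(path, index=False, date_format=_TIME_FORMAT, float_format="%.1f")


def regularize(series: GlucoseSeries, interval: int | None = None) -> GlucoseSeries:
    """Snap timestamps to the interval grid anchored at the first reading's
    midnight.

    Jitter is removed by rounding each timestamp to the nearest grid point;
    when two readings snap to the same slot the first is kept and the rest
    dropped with a warning.  Missing grid points are never filled in.
    Idempotent, and never produces more readings than it was given.
    """
    if interval is None:
        interval = series.nominal_interval
    if interval <= 0:
        raise ValueError("interval must be positive")
    if len(series) == 0:
        return GlucoseSeries(series.timestamps, series.values, nominal_interval=interval)
    anchor = series.timestamps[0].normalize()
    step_ns = int(interval) * 60 * 10**9
    offsets = series.timestamps.asi8 - anchor.value
    slots = np.rint(offsets / step_ns).astype(np.int64)
    keep = np.ones(len(slots), dtype=bool)
    keep[1:] = slots[1:] != slots[:-1]  # slots are non-decreasing: input was sorted
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        logger.warning("regularize: dropped %d reading(s) colliding on the grid", n_dropped)
    snapped = pd.DatetimeIndex(anchor.value + slots[keep] * step_ns)
    return GlucoseSeries(snapped, series.values[keep], nominal_interval=interval)
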
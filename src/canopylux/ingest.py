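"""Reading and conditioning multi-sensor light-logger exports.

Input is a long-format CSV (timestamp, sensor_id, light_lux, temp_c) as
produced by consumer lux loggers, plus a sensors metadata CSV declaring
each sensor's role (``canopy`` under 100% cover, ``open`` on bare rock)
and an optional mask-windows CSV for periods known to be bad (fouling by
settling barnacles, handling during site visits).

Processing contract, in order:

1. :func:`read_logger_csv` parses the export (tolerating a header
   preamble), skipping and counting unparseable rows;
2. :func:`align_to_grid` snaps every sensor onto one shared time grid
   without interpolating light values;
3. :func:`apply_mask_windows` blanks user-declared windows (half-open
   ``[start, end)`` so adjacent windows compose without double-masking);
4. :func:`mean_open_series` averages the open-rock sensors into the
   reference series ``I_o``, using whichever sensors report at each
   timestamp (no imputation for failed loggers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataFormatError, DomainError

__all__ = [
    "SensorMeta",
    "CsvSchema",
    "LoggerSeries",
    "MaskWindow",
    "read_logger_table",
    "read_logger_csv",
    "read_sensor_metadata",
    "read_mask_windows",
    "write_logger_csv",
    "align_to_grid",
    "mean_open_series",
    "apply_mask_windows",
    "coverage_report",
    "to_tidy_frame",
    "series_from_tidy",
]

logger = logging.getLogger(__name__)

ROLES = ("canopy", "open")


@dataclass(frozen=True)
class SensorMeta:
    sensor_id: str
    role: str
    patch_id: str | None = None
    height_above_datum: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(
                f"sensor {self.sensor_id!r}: role must be one of {ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class CsvSchema:
    """Column mapping for a logger CSV export."""

    timestamp: str = "timestamp"
    sensor_id: str = "sensor_id"
    light: str = "light_lux"
    temperature: str = "temp_c"
    timestamp_format: str | None = None  # None -> ISO-8601 / inferred


@dataclass
class LoggerSeries:
    """One sensor's time series: a datetime-indexed frame with
    ``light`` and ``temperature`` columns (NaN where missing)."""

    meta: SensorMeta
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise DomainError(
                f"sensor {self.meta.sensor_id!r}: timestamps must be strictly increasing"
            )
        light = self.data["light"]
        if (light.dropna() < 0).any():
            raise DomainError(
                f"sensor {self.meta.sensor_id!r}: negative light values present"
            )


@dataclass(frozen=True)
class MaskWindow:
    """Half-open exclusion window ``[start, end)``; ``sensor_id='*'`` matches all."""

    sensor_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    reason: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise DomainError(f"mask window start must precede end: {self}")

    def matches(self, sensor_id: str) -> bool:
        return self.sensor_id in ("*", "all", sensor_id)


def _find_header_row(path: Path, schema: CsvSchema, max_scan: int = 100) -> int:
    """Locate the header line, skipping any preamble a logger export may add."""
    with open(path, "r", encoding="utf-8-sig") as fh:
        for i, line in enumerate(fh):
            if i >= max_scan:
                break
            cells = [c.strip().strip('"') for c in line.rstrip("\n").split(",")]
            if schema.timestamp in cells and schema.sensor_id in cells:
                return i
    raise DataFormatError(
        f"{path}: no header row containing columns "
        f"{schema.timestamp!r} and {schema.sensor_id!r}"
    )


def read_logger_table(path, schema: CsvSchema | None = None) -> tuple[pd.DataFrame, int]:
    """Parse a long-format logger CSV into a tidy frame.

    Returns ``(frame, n_skipped)`` where the frame has columns
    ``timestamp, sensor_id, light, temperature`` and ``n_skipped`` counts
    rows dropped for unparseable timestamps or missing sensor ids
    (negative light values are additionally blanked to missing).
    """
    schema = schema or CsvSchema()
    path = Path(path)
    header_row = _find_header_row(path, schema)
    raw = pd.read_csv(path, skiprows=header_row, dtype=str, encoding="utf-8-sig")
    for col in (schema.timestamp, schema.sensor_id, schema.light):
        if col not in raw.columns:
            raise DataFormatError(f"{path}: missing mandatory column {col!r}")
    ts = pd.to_datetime(raw[schema.timestamp], format=schema.timestamp_format, errors="coerce")
    sensor = raw[schema.sensor_id].astype("string").str.strip()
    bad = ts.isna() | sensor.isna() | (sensor == "")
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("%s: skipped %d unparseable row(s)", path, n_skipped)
    light = pd.to_numeric(raw[schema.light], errors="coerce")
    negative = light < 0
    if negative.any():
        logger.warning("%s: %d negative light value(s) set to missing", path, int(negative.sum()))
        light[negative] = np.nan
    if schema.temperature in raw.columns:
        temperature = pd.to_numeric(raw[schema.temperature], errors="coerce")
    else:
        temperature = pd.Series(np.nan, index=raw.index)
    frame = pd.DataFrame(
        {
            "timestamp": ts,
            "sensor_id": sensor,
            "light": light,
            "temperature": temperature,
        }
    )[~bad].reset_index(drop=True)
    return frame, n_skipped


def series_from_tidy(
    frame: pd.DataFrame,
    metadata: Mapping[str, SensorMeta] | None = None,
    default_role: str = "open",
) -> list[LoggerSeries]:
    """Split a tidy (timestamp, sensor_id, light, temperature) frame per sensor."""
    out: list[LoggerSeries] = []
    for sensor_id, group in frame.groupby("sensor_id", sort=True):
        if metadata is not None and sensor_id in metadata:
            meta = metadata[sensor_id]
        else:
            meta = SensorMeta(sensor_id=str(sensor_id), role=default_role)
        data = (
            group.set_index("timestamp")[["light", "temperature"]]
            .sort_index()
        )
        data = data[~data.index.duplicated(keep="first")]
        out.append(LoggerSeries(meta=meta, data=data))
    return out


def read_logger_csv(
    path,
    schema: CsvSchema | None = None,
    metadata: Mapping[str, SensorMeta] | None = None,
    default_role: str = "open",
) -> list[LoggerSeries]:
    """Read a logger CSV export into one :class:`LoggerSeries` per sensor.

    Roles normally come from the sensors metadata CSV
    (:func:`read_sensor_metadata`); sensors absent from ``metadata`` get
    ``default_role``.
    """
    frame, _ = read_logger_table(path, schema)
    return series_from_tidy(frame, metadata=metadata, default_role=default_role)


def read_sensor_metadata(path) -> dict[str, SensorMeta]:
    """Read the sensors CSV (sensor_id, role, patch_id, height_above_datum_m)."""
    raw = pd.read_csv(path, dtype=str, encoding="utf-8-sig")
    for col in ("sensor_id", "role"):
        if col not in raw.columns:
            raise DataFormatError(f"{path}: missing mandatory column {col!r}")
    out: dict[str, SensorMeta] = {}
    for _, row in raw.iterrows():
        sensor_id = str(row["sensor_id"]).strip()
        height = row.get("height_above_datum_m")
        out[sensor_id] = SensorMeta(
            sensor_id=sensor_id,
            role=str(row["role"]).strip(),
            patch_id=(str(row["patch_id"]).strip() if "patch_id" in raw.columns and pd.notna(row["patch_id"]) else None),
            height_above_datum=(float(height) if pd.notna(height) else None),
        )
    return out


def read_mask_windows(path) -> list[MaskWindow]:
    """Read a mask-windows CSV (sensor_id, start, end, reason)."""
    raw = pd.read_csv(path, dtype=str, encoding="utf-8-sig")
    for col in ("sensor_id", "start", "end"):
        if col not in raw.columns:
            raise DataFormatError(f"{path}: missing mandatory column {col!r}")
    return [
        MaskWindow(
            sensor_id=str(row["sensor_id"]).strip(),
            start=pd.Timestamp(row["start"]),
            end=pd.Timestamp(row["end"]),
            reason=str(row.get("reason", "") or ""),
        )
        for _, row in raw.iterrows()
    ]


def to_tidy_frame(series_list: Sequence[LoggerSeries]) -> pd.DataFrame:
    """Concatenate per-sensor series back into one tidy long frame."""
    parts = []
    for s in series_list:
        part = s.data.rename_axis("timestamp").reset_index()
        part.insert(1, "sensor_id", s.meta.sensor_id)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_logger_csv(series_list: Sequence[LoggerSeries], path, schema: CsvSchema | None = None) -> None:
    """Write series in the canonical long CSV schema (ISO-8601 timestamps)."""
    schema = schema or CsvSchema()
    frame = to_tidy_frame(series_list).rename(
        columns={
            "timestamp": schema.timestamp,
            "sensor_id": schema.sensor_id,
            "light": schema.light,
            "temperature": schema.temperature,
        }
    )
    frame = frame.dropna(subset=[schema.light, schema.temperature], how="all")
    frame.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def align_to_grid(
    series_list: Sequence[LoggerSeries],
    interval: str | pd.Timedelta = "30min",
    tolerance: str | pd.Timedelta = "5min",
) -> list[LoggerSeries]:
    """Re-index every sensor onto one shared regular grid.

    The grid runs at ``interval`` (which must divide 24 h evenly) from the
    midnight before the earliest record to the midnight after the latest,
    shared by all sensors.  Timestamps within ``tolerance`` of a grid
    point snap to it; others are dropped.  Grid slots with no record
    become missing -- light is never interpolated.
    """
    if not series_list:
        raise DomainError("align_to_grid requires at least one series")
    interval = pd.Timedelta(interval)
    tolerance = pd.Timedelta(tolerance)
    if interval <= pd.Timedelta(0) or pd.Timedelta(days=1) % interval != pd.Timedelta(0):
        raise DomainError(f"interval must divide 24 h evenly, got {interval}")
    start = min(s.data.index[0] for s in series_list if len(s.data)).floor("D")
    end = max(s.data.index[-1] for s in series_list if len(s.data)).ceil("D")
    grid = pd.date_range(start, end, freq=interval)
    out = []
    for s in series_list:
        snapped = s.data.index.round(interval)
        keep = np.abs(s.data.index - snapped) <= tolerance
        data = s.data[keep].copy()
        data.index = snapped[keep]
        data = data[~data.index.duplicated(keep="first")]
        out.append(LoggerSeries(meta=s.meta, data=data.reindex(grid)))
    return out


def mean_open_series(series_list: Sequence[LoggerSeries]) -> pd.Series:
    """Reference open-rock light ``I_o``: per-timestamp mean of open sensors.

    At each timestamp the mean runs over the open sensors with a present
    value (sensors do fail in the field); missing where none report.
    """
    opens = [s for s in series_list if s.meta.role == "open"]
    if not opens:
        raise ConfigError("no sensors with role 'open'; cannot form the I_o reference")
    wide = pd.concat(
        {s.meta.sensor_id: s.data["light"] for s in opens}, axis=1
    )
    return wide.mean(axis=1, skipna=True)


def apply_mask_windows(
    series: LoggerSeries, windows: Iterable[MaskWindow]
) -> tuple[LoggerSeries, int]:
    """Blank light values inside matching windows.

    Returns the masked series and the number of previously-present light
    values that were removed.  Windows are half-open ``[start, end)``.
    Idempotent: re-masking removes nothing further.
    """
    data = series.data.copy()
    mask = np.zeros(len(data), dtype=bool)
    for w in windows:
        if w.matches(series.meta.sensor_id):
            mask |= np.asarray((data.index >= w.start) & (data.index < w.end))
    n_masked = int((mask & data["light"].notna().to_numpy()).sum())
    data.loc[mask, "light"] = np.nan
    return LoggerSeries(meta=series.meta, data=data), n_masked


def coverage_report(series_list: Sequence[LoggerSeries]) -> pd.DataFrame:
    """Per-sensor data coverage: rows, present light values, fraction present."""
    rows = []
    for s in series_list:
        n = len(s.data)
        present = int(s.data["light"].notna().sum())
        rows.append(
            {
                "sensor_id": s.meta.sensor_id,
                "role": s.meta.role,
                "n_slots": n,
                "n_present": present,
                "coverage": present / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
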
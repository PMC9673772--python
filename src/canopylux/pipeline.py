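"""End-to-end index and trend computation.

Thin orchestration over :mod:`ingest`, :mod:`solar`, :mod:`model` and
:mod:`trend`: align the loggers, form the open-rock reference, compute
the per-canopy-sensor attenuation index with the night/zero and
crepuscular exclusion rules, then LOESS-smooth each sensor's series and
summarise the seasonal extrema across sensors.  Every record is
accounted to exactly one category (masked, night/zero, crepuscular,
retained) per canopy sensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import trend as trend_mod
from .errors import ConfigError, DomainError
from .ingest import LoggerSeries, MaskWindow, align_to_grid, apply_mask_windows, mean_open_series
from .model import attenuation_index
from .solar import SiteLocation, day_of_year, daylight_fraction

__all__ = ["FilterCounts", "compute_index_table", "trend_summary"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterCounts:
    """Per-sensor accounting of where records went; categories are
    disjoint and sum to ``total``."""

    total: int
    masked: int
    night_zero: int
    crepuscular: int
    retained: int

    def __post_init__(self) -> None:
        assert self.masked + self.night_zero + self.crepuscular + self.retained == self.total

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "masked": self.masked,
            "night_zero": self.night_zero,
            "crepuscular": self.crepuscular,
            "retained": self.retained,
        }


def compute_index_table(
    series_list: Sequence[LoggerSeries],
    site: SiteLocation,
    masks: Iterable[MaskWindow] = (),
    interval: str = "30min",
    tolerance: str = "5min",
    light_threshold: float = 0.0,
    crepuscular_fraction: float = 0.1,
    anchor_year: int | None = None,
) -> tuple[pd.DataFrame, dict[str, FilterCounts]]:
    """Attenuation-index series for every canopy sensor.

    Returns a long frame (``sensor_id, timestamp, day_of_year, index``)
    of retained records only, plus per-sensor :class:`FilterCounts`.
    The open-rock reference ``I_o`` is the per-timestamp mean of the
    (mask-filtered) open sensors.
    """
    roles = {s.meta.role for s in series_list}
    if "canopy" not in roles:
        raise ConfigError("no sensors with role 'canopy'")
    if "open" not in roles:
        raise ConfigError("no sensors with role 'open'")
    if not (0 <= crepuscular_fraction < 0.5):
        raise DomainError(
            f"crepuscular_fraction must be in [0, 0.5), got {crepuscular_fraction!r}"
        )
    aligned = align_to_grid(series_list, interval=interval, tolerance=tolerance)
    masks = list(masks)
    masked_counts: dict[str, int] = {}
    masked_series = []
    masked_flags: dict[str, np.ndarray] = {}
    for s in aligned:
        before = s.data["light"].notna().to_numpy()
        ms, n_masked = apply_mask_windows(s, masks)
        masked_counts[s.meta.sensor_id] = n_masked
        masked_flags[s.meta.sensor_id] = before & ms.data["light"].isna().to_numpy()
        masked_series.append(ms)

    i_open = mean_open_series(masked_series)
    grid = i_open.index
    if anchor_year is None:
        anchor_year = int(grid[0].year)
    doy = day_of_year(grid, anchor_year=anchor_year)
    dayfrac = daylight_fraction(grid, site)
    in_band = (dayfrac >= crepuscular_fraction) & (dayfrac <= 1.0 - crepuscular_fraction)

    rows = []
    counts: dict[str, FilterCounts] = {}
    i_open_vals = i_open.to_numpy()
    for s in masked_series:
        if s.meta.role != "canopy":
            continue
        i_c = s.data["light"].to_numpy()
        masked_here = masked_flags[s.meta.sensor_id]
        valid = (
            np.isfinite(i_open_vals)
            & np.isfinite(i_c)
            & (i_open_vals > light_threshold)
            & (i_c > light_threshold)
        )
        night_zero = ~masked_here & ~valid
        crepuscular = valid & ~in_band & ~masked_here
        retained = valid & in_band & ~masked_here
        counts[s.meta.sensor_id] = FilterCounts(
            total=len(grid),
            masked=int(masked_here.sum()),
            night_zero=int(night_zero.sum()),
            crepuscular=int(crepuscular.sum()),
            retained=int(retained.sum()),
        )
        if not retained.any():
            logger.warning("sensor %s: no records retained", s.meta.sensor_id)
            continue
        index_vals = attenuation_index(
            i_open_vals[retained], i_c[retained], threshold=light_threshold
        )
        rows.append(
            pd.DataFrame(
                {
                    "sensor_id": s.meta.sensor_id,
                    "timestamp": grid[retained],
                    "day_of_year": doy[retained],
                    "index": index_vals,
                }
            )
        )
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["sensor_id", "timestamp", "day_of_year", "index"])
    for sensor_id, c in counts.items():
        logger.info(
            "sensor %s: retained %d / %d (masked %d, night/zero %d, crepuscular %d)",
            sensor_id, c.retained, c.total, c.masked, c.night_zero, c.crepuscular,
        )
    return table, counts


def trend_summary(
    index_table: pd.DataFrame,
    span: float = 0.4,
    degree: int = 1,
    robustness: int = 0,
    k_a: float | None = None,
    grid_step_days: float = 1.0,
    aggregate: str = "points",
) -> tuple[pd.DataFrame, dict]:
    """LOESS trends per canopy sensor and a cross-sensor summary.

    ``aggregate='points'`` smooths the retained half-hourly index values
    directly; ``'daily-median'`` pre-aggregates each sensor to daily
    medians first (faster, slightly smoother).  Trends are evaluated on a
    uniform grid of ``grid_step_days`` for reporting and extrema
    extraction.  Sensors with too few points are dropped with a warning.
    Returns ``(trend_frame, summary_dict)``; the summary carries
    index-scale extrema and, when ``k_a`` is given, the same extrema on
    the thallus-area-index scale.
    """
    if aggregate not in ("points", "daily-median"):
        raise ConfigError(f"aggregate must be 'points' or 'daily-median', got {aggregate!r}")
    trend_frames = []
    extrema = []
    sensors_used = []
    for sensor_id, group in index_table.groupby("sensor_id", sort=True):
        x = group["day_of_year"].to_numpy(dtype=float)
        y = group["index"].to_numpy(dtype=float)
        if aggregate == "daily-median":
            day_bin = np.floor(x)
            agg = pd.DataFrame({"day": day_bin, "y": y}).groupby("day")["y"].median()
            x, y = agg.index.to_numpy() + 0.5, agg.to_numpy()
        eval_x = np.arange(np.floor(x.min()), np.ceil(x.max()) + 1e-9, grid_step_days) + 0.5
        try:
            fitted = trend_mod.loess_smooth(
                x, y, span=span, degree=degree, robustness=robustness, eval_x=eval_x
            )
        except DomainError as exc:
            logger.warning("sensor %s dropped from trend summary: %s", sensor_id, exc)
            continue
        trend_frames.append(
            pd.DataFrame(
                {"sensor_id": sensor_id, "day_of_year": eval_x, "smoothed_index": fitted}
            )
        )
        extrema.append(trend_mod.extract_extrema(eval_x, fitted))
        sensors_used.append(sensor_id)
    if not extrema:
        raise DomainError("no sensor had enough points for a trend")
    summary = trend_mod.summarize_sensors(extrema)
    out: dict = {"index_scale": summary.as_dict(), "sensors": sensors_used}
    out["per_sensor"] = {
        sid: {
            "peak_value": e.peak_value,
            "peak_day": e.peak_day,
            "trough_value": e.trough_value,
            "trough_day": e.trough_day,
        }
        for sid, e in zip(sensors_used, extrema)
    }
    if k_a is not None:
        scaled = trend_mod.summarize_sensors(
            trend_mod.Extrema(
                peak_value=e.peak_value / k_a,
                peak_day=e.peak_day,
                trough_value=e.trough_value / k_a,
                trough_day=e.trough_day,
            )
            for e in extrema
        )
        out["tai_scale"] = scaled.as_dict()
        out["k_a"] = k_a
    return pd.concat(trend_frames, ignore_index=True), out
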
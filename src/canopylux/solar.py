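"""Solar geometry and daylight-based filtering.

Dawn and dusk default to the zero-elevation crossing of the sun's centre
with no atmospheric refraction (a ``refraction=True`` switch uses the
standard -0.833 deg rise/set altitude instead).  Clock time is corrected
to true solar time with the site longitude and the equation of time, so
the daylight-fraction axis is centred on solar noon rather than clock
noon.  Declination and the equation of time use Spencer's Fourier series,
accurate to well under a minute for rise/set work.

Two data-cleaning rules live here:

* **night/zero masking** -- the index ``ln(I_o/I_c)`` is undefined when
  either sensor reads zero (every night), so such records become missing;
* **crepuscular trimming** -- index values in the first and last tenth of
  daylight are unreliable (a systematic dip near dawn and dusk) and are
  removed before trend fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "SiteLocation",
    "DaylightWindow",
    "day_of_year",
    "solar_declination",
    "equation_of_time",
    "solar_elevation",
    "daylight_window",
    "daylight_fraction",
    "fraction_in_window",
    "night_zero_mask",
    "crepuscular_filter",
]

#: Sun altitude (degrees) defining rise/set when refraction is modelled.
REFRACTED_RISE_SET_ALTITUDE = -0.833


@dataclass(frozen=True)
class SiteLocation:
    """Geographic site of a logger deployment.

    ``utc_offset`` is the fixed offset (hours) of the naive timestamps in
    the data from UTC; logger clocks normally run on standard time, so a
    single offset suffices.
    """

    latitude: float
    longitude: float
    utc_offset: float = 0.0

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise DomainError(f"latitude out of range [-90, 90]: {self.latitude!r}")
        if not -180 <= self.longitude <= 180:
            raise DomainError(f"longitude out of range [-180, 180]: {self.longitude!r}")


@dataclass(frozen=True)
class DaylightWindow:
    """Dawn/dusk pair for one calendar day at a site (local clock time)."""

    date: _date
    dawn: pd.Timestamp
    dusk: pd.Timestamp
    daylength_hours: float


def day_of_year(timestamps, anchor_year: int | None = None):
    """Fractional day of year; 12:00 on 12 June maps to 163.5.

    Jan 1 00:00 of the anchor year is day 1.0, and the count continues
    past 365/366 into following years so multi-year deployments keep a
    monotone axis.  ``anchor_year`` defaults to the year of the (first)
    timestamp.
    """
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
    if anchor_year is None:
        anchor_year = int(ts[0].year)
    origin = pd.Timestamp(year=anchor_year, month=1, day=1)
    doy = (ts - origin) / pd.Timedelta(days=1) + 1.0
    doy = np.asarray(doy, dtype=float)
    if np.ndim(timestamps) == 0 and not isinstance(timestamps, (list, np.ndarray, pd.Index)):
        return float(doy[0])
    return doy


def _fractional_year(times: pd.DatetimeIndex) -> np.ndarray:
    """Angle (radians) of the date within the year, per Spencer's series."""
    doy = times.dayofyear.to_numpy(dtype=float)
    hour = (times - times.normalize()) / pd.Timedelta(hours=1)
    return 2.0 * np.pi / 365.0 * (doy - 1.0 + (np.asarray(hour) - 12.0) / 24.0)


def solar_declination(times) -> np.ndarray:
    """Solar declination (radians) via Spencer's Fourier series."""
    g = _fractional_year(pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]"))))
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.001480 * np.sin(3 * g)
    )


def equation_of_time(times) -> np.ndarray:
    """Equation of time (minutes, apparent minus mean solar time)."""
    g = _fractional_year(pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]"))))
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def solar_elevation(times, site: SiteLocation) -> np.ndarray:
    """Solar elevation angle (degrees) for naive local timestamps at a site."""
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]")))
    decl = solar_declination(ts)
    eqt = equation_of_time(ts)
    clock_min = np.asarray((ts - ts.normalize()) / pd.Timedelta(minutes=1))
    true_solar_min = clock_min + eqt + 4.0 * site.longitude - 60.0 * site.utc_offset
    hour_angle = np.deg2rad(true_solar_min / 4.0 - 180.0)
    lat = np.deg2rad(site.latitude)
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    return np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def daylight_window(date, site: SiteLocation, refraction: bool = False) -> DaylightWindow:
    """Dawn, dusk and daylength for one calendar day.

    Polar day returns a full 24 h window, polar night a zero-length
    window centred on solar noon.
    """
    day = pd.Timestamp(date).normalize()
    noon = day + pd.Timedelta(hours=12)
    decl = float(solar_declination([noon])[0])
    eqt = float(equation_of_time([noon])[0])
    # Solar noon in local clock minutes from midnight (longitude positive east).
    solar_noon_min = 720.0 - 4.0 * site.longitude + 60.0 * site.utc_offset - eqt
    lat = np.deg2rad(site.latitude)
    altitude = np.deg2rad(REFRACTED_RISE_SET_ALTITUDE if refraction else 0.0)
    denom = np.cos(lat) * np.cos(decl)
    if denom == 0:
        cos_h0 = np.inf
    else:
        cos_h0 = (np.sin(altitude) - np.sin(lat) * np.sin(decl)) / denom
    if cos_h0 >= 1.0:  # sun never reaches the rise/set altitude: polar night
        half_width_min = 0.0
    elif cos_h0 <= -1.0:  # polar day
        half_width_min = 720.0
    else:
        half_width_min = np.rad2deg(np.arccos(cos_h0)) * 4.0
    dawn = day + pd.Timedelta(minutes=solar_noon_min - half_width_min)
    dusk = day + pd.Timedelta(minutes=solar_noon_min + half_width_min)
    return DaylightWindow(
        date=day.date(), dawn=dawn, dusk=dusk, daylength_hours=half_width_min / 30.0
    )


def fraction_in_window(timestamp, window: DaylightWindow) -> float:
    """Position of a timestamp within a daylight window (dawn 0, dusk 1).

    Values outside [0, 1] indicate night; a zero-length (polar night)
    window maps everything to NaN.
    """
    if window.daylength_hours <= 0:
        return float("nan")
    return float(
        (pd.Timestamp(timestamp) - window.dawn)
        / pd.Timedelta(hours=window.daylength_hours)
    )


def daylight_fraction(timestamps, site: SiteLocation, refraction: bool = False) -> np.ndarray:
    """Daylight fraction for each timestamp (dawn of its day = 0, dusk = 1).

    NaN where the day has no daylight (polar night); values < 0 or > 1
    are night-time records on ordinary days.
    """
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
    out = np.full(len(ts), np.nan)
    days = ts.normalize()
    for day in days.unique():
        window = daylight_window(day, site, refraction=refraction)
        sel = days == day
        if window.daylength_hours <= 0:
            continue
        out[sel] = (ts[sel] - window.dawn) / pd.Timedelta(hours=window.daylength_hours)
    return out


def night_zero_mask(i_open, i_canopy, threshold: float = 0.0) -> np.ndarray:
    """Boolean mask of records usable for the index ``ln(I_o/I_c)``.

    False where either reading is missing or ``<= threshold`` -- every
    night record, plus any reading at or below a configured sensor noise
    floor.  Applied to both sensors: a zero open reading with a positive
    canopy reading would make the index infinite.
    """
    i_o = np.asarray(i_open, dtype=float)
    i_c = np.asarray(i_canopy, dtype=float)
    return np.isfinite(i_o) & np.isfinite(i_c) & (i_o > threshold) & (i_c > threshold)


def crepuscular_filter(
    index_series: pd.Series,
    site: SiteLocation,
    fraction: float = 0.1,
    refraction: bool = False,
) -> pd.Series:
    """Remove index values from the edges of daylight.

    Records whose daylight fraction is ``< fraction`` or ``> 1 - fraction``
    (night included) become missing.  ``fraction=0.1`` drops the first and
    last tenth of daylight, where the index shows a systematic crepuscular
    dip; ``fraction=0`` removes night points only.  Idempotent.
    """
    if not (0 <= fraction < 0.5):
        raise DomainError(f"crepuscular fraction must be in [0, 0.5), got {fraction!r}")
    frac = daylight_fraction(index_series.index, site, refraction=refraction)
    keep = (frac >= fraction) & (frac <= 1.0 - fraction)
    out = index_series.copy()
    out[~keep] = np.nan
    return out
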
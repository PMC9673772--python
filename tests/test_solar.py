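"""Solar geometry against an independent NOAA-style oracle, plus the
daylight filters."""

import math

import numpy as np
import pandas as pd
import pytest

from canopylux.errors import DomainError
from canopylux.solar import (
    SiteLocation,
    crepuscular_filter,
    day_of_year,
    daylight_fraction,
    daylight_window,
    fraction_in_window,
    night_zero_mask,
    solar_elevation,
)

GALWAY = SiteLocation(latitude=53.246, longitude=-9.221, utc_offset=0.0)


# --- independent oracle: NOAA solar calculator (Julian-century formulation) ---

def _noaa_sun_minutes(date, lat, lon, utc_offset, zenith=90.0):
    """Sunrise/sunset in local clock minutes via the NOAA spreadsheet algorithm."""
    jd = pd.Timestamp(date).to_julian_date() + 0.5 - lon / 360.0 - utc_offset / 24.0
    jc = (jd - 2451545.0) / 36525.0
    gml = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eqc = (
        math.sin(math.radians(gma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gma)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gma)) * 0.000289
    )
    true_long = gml + eqc
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    mean_ob = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_ob + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    eot = 4.0 * math.degrees(
        var_y * math.sin(2.0 * math.radians(gml))
        - 2.0 * ecc * math.sin(math.radians(gma))
        + 4.0 * ecc * var_y * math.sin(math.radians(gma)) * math.cos(2.0 * math.radians(gml))
        - 0.5 * var_y**2 * math.sin(4.0 * math.radians(gml))
        - 1.25 * ecc**2 * math.sin(2.0 * math.radians(gma))
    )
    cos_ha = (
        math.cos(math.radians(zenith)) / (math.cos(math.radians(lat)) * math.cos(math.radians(decl)))
        - math.tan(math.radians(lat)) * math.tan(math.radians(decl))
    )
    if not -1.0 < cos_ha < 1.0:
        return None  # polar day or night
    ha = math.degrees(math.acos(cos_ha))
    noon = 720.0 - 4.0 * lon - eot + 60.0 * utc_offset
    return noon - 4.0 * ha, noon + 4.0 * ha


ORACLE_GRID = [
    (lat, date)
    for lat in (-60.0, -30.0, 0.0, 30.0, 53.246, 65.0)
    for date in ("2019-03-21", "2019-06-21", "2019-09-23", "2019-12-21", "2019-02-01", "2019-08-15")
]


@pytest.mark.parametrize("lat, date", ORACLE_GRID)
def test_daylight_window_matches_noaa_oracle(lat, date):
    site = SiteLocation(latitude=lat, longitude=-9.221, utc_offset=0.0)
    oracle = _noaa_sun_minutes(date, site.latitude, site.longitude, site.utc_offset)
    if oracle is None:
        pytest.skip("polar day/night at this latitude/date")
    window = daylight_window(date, site)
    day = pd.Timestamp(date)
    dawn_min = (window.dawn - day) / pd.Timedelta(minutes=1)
    dusk_min = (window.dusk - day) / pd.Timedelta(minutes=1)
    assert abs(dawn_min - oracle[0]) <= 5.0
    assert abs(dusk_min - oracle[1]) <= 5.0


def test_daylength_reference_values():
    # equator at equinox
    assert daylight_window("2019-03-21", SiteLocation(0, 0)).daylength_hours == pytest.approx(
        12.0, abs=0.2
    )
    # Galway midsummer
    assert daylight_window("2019-06-21", GALWAY).daylength_hours == pytest.approx(16.9, abs=0.3)
    # polar night
    assert daylight_window("2019-12-21", SiteLocation(80, 0)).daylength_hours == 0.0
    # polar day
    assert daylight_window("2019-06-21", SiteLocation(80, 0)).daylength_hours == 24.0


def test_daylength_solstice_vs_equinox_by_hemisphere():
    for lat in (45.0, -45.0):
        site = SiteLocation(lat, 0.0)
        equinox = daylight_window("2019-03-21", site).daylength_hours
        june = daylight_window("2019-06-21", site).daylength_hours
        if lat > 0:
            assert june > equinox
        else:
            assert june < equinox


def test_window_symmetric_about_solar_noon():
    w = daylight_window("2019-04-10", GALWAY)
    mid = w.dawn + (w.dusk - w.dawn) / 2
    elev_mid = solar_elevation([mid], GALWAY)[0]
    # solar noon is the daily elevation maximum: slightly before/after is lower
    for dt in (pd.Timedelta(minutes=40), -pd.Timedelta(minutes=40)):
        assert solar_elevation([mid + dt], GALWAY)[0] < elev_mid


def test_day_of_year_anchor_and_continuation():
    assert day_of_year(pd.Timestamp("2019-06-12 12:00")) == pytest.approx(163.5)
    assert day_of_year(pd.Timestamp("2019-01-01 00:00")) == pytest.approx(1.0)
    # second deployment year continues past 365
    assert day_of_year(pd.Timestamp("2020-01-10 00:00"), anchor_year=2019) == pytest.approx(375.0)


def test_daylight_fraction_endpoints():
    w = daylight_window("2019-06-21", GALWAY)
    assert fraction_in_window(w.dawn, w) == pytest.approx(0.0, abs=1e-9)
    assert fraction_in_window(w.dusk, w) == pytest.approx(1.0, abs=1e-9)
    mid = w.dawn + (w.dusk - w.dawn) / 2
    assert fraction_in_window(mid, w) == pytest.approx(0.5, abs=1e-9)
    assert fraction_in_window(w.dusk + pd.Timedelta(hours=1), w) > 1.0  # night
    polar = daylight_window("2019-12-21", SiteLocation(80, 0))
    assert math.isnan(fraction_in_window(pd.Timestamp("2019-12-21 12:00"), polar))


def test_night_zero_mask_rules():
    i_o = np.array([100.0, 0.0, 50.0, np.nan, 30.0])
    i_c = np.array([10.0, 20.0, 0.0, 5.0, np.nan])
    assert list(night_zero_mask(i_o, i_c)) == [True, False, False, False, False]
    # raised threshold removes low but nonzero readings from either sensor
    assert list(night_zero_mask(i_o, i_c, threshold=40.0)) == [False, False, False, False, False]


def _index_series_over_day(date="2019-06-21", freq="30min"):
    times = pd.date_range(f"{date} 00:00", f"{date} 23:30", freq=freq)
    return pd.Series(1.0, index=times)


def test_crepuscular_filter_bands():
    series = _index_series_over_day()
    w = daylight_window("2019-06-21", GALWAY)
    filtered = crepuscular_filter(series, GALWAY, fraction=0.1)
    frac = daylight_fraction(series.index, GALWAY)
    # removed exactly where the daylight fraction is out of [0.1, 0.9] (night included)
    expected_removed = ~((frac >= 0.1) & (frac <= 0.9))
    assert list(filtered.isna()) == list(expected_removed)
    # a point 5% into daylight is removed at fraction=0.1
    early = w.dawn + pd.Timedelta(hours=0.05 * w.daylength_hours)
    s_early = pd.Series([1.0], index=[early])
    assert crepuscular_filter(s_early, GALWAY, fraction=0.1).isna().all()
    # midday is retained
    mid = w.dawn + pd.Timedelta(hours=0.5 * w.daylength_hours)
    assert not crepuscular_filter(pd.Series([1.0], index=[mid]), GALWAY, 0.1).isna().any()


def test_crepuscular_filter_zero_fraction_removes_only_night():
    series = _index_series_over_day()
    filtered = crepuscular_filter(series, GALWAY, fraction=0.0)
    frac = daylight_fraction(series.index, GALWAY)
    assert list(filtered.isna()) == list(~((frac >= 0) & (frac <= 1)))


def test_crepuscular_filter_monotone_and_idempotent():
    series = _index_series_over_day()
    removed = [
        int(crepuscular_filter(series, GALWAY, fraction=f).isna().sum())
        for f in (0.3, 0.2, 0.1, 0.0)
    ]
    assert removed == sorted(removed, reverse=True)  # fewer removed as fraction shrinks
    once = crepuscular_filter(series, GALWAY, fraction=0.1)
    twice = crepuscular_filter(once, GALWAY, fraction=0.1)
    pd.testing.assert_series_equal(once, twice)
    with pytest.raises(DomainError):
        crepuscular_filter(series, GALWAY, fraction=0.5)


def test_site_location_validation():
    with pytest.raises(DomainError):
        SiteLocation(latitude=91.0, longitude=0.0)
    with pytest.raises(DomainError):
        SiteLocation(latitude=0.0, longitude=300.0)
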
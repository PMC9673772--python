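"""Logger CSV ingestion, grid alignment, open-sensor mean and masking."""

import numpy as np
import pandas as pd
import pytest

from canopylux.errors import ConfigError, DataFormatError, DomainError
from canopylux.ingest import (
    CsvSchema,
    LoggerSeries,
    MaskWindow,
    SensorMeta,
    align_to_grid,
    apply_mask_windows,
    coverage_report,
    mean_open_series,
    read_logger_csv,
    read_logger_table,
    read_mask_windows,
    read_sensor_metadata,
    write_logger_csv,
)


def make_series(sensor_id="s1", role="open", times=None, light=None, temp=None):
    if times is None:
        times = pd.date_range("2019-06-01 10:00", periods=6, freq="30min")
    if light is None:
        light = np.full(len(times), 100.0)
    if temp is None:
        temp = np.full(len(times), 12.0)
    return LoggerSeries(
        meta=SensorMeta(sensor_id=sensor_id, role=role),
        data=pd.DataFrame({"light": light, "temperature": temp}, index=pd.DatetimeIndex(times)),
    )


def test_read_logger_csv_toy_file(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "timestamp,sensor_id,light_lux,temp_c\n"
        "2019-06-01T10:00:00,s1,100.5,12.1\n"
        "2019-06-01T10:30:00,s1,200.25,12.2\n"
        "2019-06-01T11:00:00,s1,0,12.3\n"
    )
    series = read_logger_csv(path)
    assert len(series) == 1
    assert len(series[0].data) == 3
    assert series[0].data["light"].tolist() == [100.5, 200.25, 0.0]


def test_read_logger_csv_skips_malformed_rows(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "timestamp,sensor_id,light_lux,temp_c\n"
        "2019-06-01T10:00:00,s1,100,12.1\n"
        "not-a-timestamp,s1,200,12.2\n"
        "2019-06-01T11:00:00,s1,300,12.3\n"
    )
    frame, n_skipped = read_logger_table(path)
    assert n_skipped == 1
    assert len(frame) == 2


def test_read_logger_csv_tolerates_header_preamble(tmp_path):
    path = tmp_path / "export.csv"
    path.write_text(
        "Logger export v2.1\n"
        "Site: shore A,,,\n"
        "timestamp,sensor_id,light_lux,temp_c\n"
        "2019-06-01T10:00:00,s1,100,12.1\n"
    )
    series = read_logger_csv(path)
    assert len(series[0].data) == 1


def test_read_logger_csv_missing_column_names_the_column(tmp_path):
    path = tmp_path / "missing.csv"
    path.write_text("timestamp,sensor_id,temp_c\n2019-06-01T10:00:00,s1,12.1\n")
    with pytest.raises(DataFormatError, match="light_lux"):
        read_logger_csv(path)


def test_logger_csv_round_trip_exact(tmp_path):
    rng = np.random.default_rng(5)
    times = pd.date_range("2019-06-01", periods=20, freq="30min")
    original = [
        make_series("a", "open", times, rng.integers(0, 100000, 20).astype(float)),
        make_series("b", "canopy", times, np.round(rng.uniform(0, 5000, 20), 4)),
    ]
    path = tmp_path / "round.csv"
    write_logger_csv(original, path)
    meta = {s.meta.sensor_id: s.meta for s in original}
    recovered = {s.meta.sensor_id: s for s in read_logger_csv(path, metadata=meta)}
    for s in original:
        r = recovered[s.meta.sensor_id]
        assert r.meta.role == s.meta.role
        pd.testing.assert_series_equal(
            r.data["light"], s.data["light"], check_names=False, check_freq=False
        )


def test_sensor_metadata_and_mask_csvs(tmp_path):
    (tmp_path / "sensors.csv").write_text(
        "sensor_id,role,patch_id,height_above_datum_m\ns1,open,P1,1.8\ns2,canopy,P2,\n"
    )
    meta = read_sensor_metadata(tmp_path / "sensors.csv")
    assert meta["s1"].role == "open" and meta["s1"].height_above_datum == 1.8
    assert meta["s2"].height_above_datum is None
    (tmp_path / "masks.csv").write_text(
        "sensor_id,start,end,reason\ns1,2019-06-01T10:00,2019-06-01T11:00,barnacles\n"
    )
    windows = read_mask_windows(tmp_path / "masks.csv")
    assert windows[0].reason == "barnacles"
    with pytest.raises(ConfigError):
        SensorMeta("s3", "submerged")


def test_align_identical_grids_unchanged():
    a = make_series("a")
    aligned = align_to_grid([a], interval="30min")
    present = aligned[0].data["light"].dropna()
    pd.testing.assert_series_equal(present, a.data["light"], check_freq=False)


def test_align_missing_slot_becomes_nan():
    times = pd.date_range("2019-06-01 10:00", periods=6, freq="30min").delete(2)
    a = make_series("a", times=times, light=np.arange(5, dtype=float))
    aligned = align_to_grid([a])[0]
    assert np.isnan(aligned.data.loc["2019-06-01 11:00", "light"])
    assert aligned.data.loc["2019-06-01 11:30", "light"] == 2.0


@pytest.mark.parametrize("offset_min, kept", [(1, True), (4, True), (7, False)])
def test_align_snap_tolerance(offset_min, kept):
    times = pd.date_range("2019-06-01 10:00", periods=4, freq="30min") + pd.Timedelta(
        minutes=offset_min
    )
    a = make_series("a", times=times, light=np.arange(4, dtype=float))
    aligned = align_to_grid([a], interval="30min", tolerance="5min")[0]
    assert (aligned.data["light"].notna().sum() == 4) == kept


def test_align_never_invents_light_values():
    rng = np.random.default_rng(1)
    times = pd.date_range("2019-06-01", periods=40, freq="30min")
    jitter = pd.to_timedelta(rng.integers(-8, 8, 40), unit="min")
    vals = rng.uniform(0, 1000, 40)
    a = make_series("a", times=(times + jitter).sort_values(), light=vals)
    aligned = align_to_grid([a])[0]
    out_vals = aligned.data["light"].dropna().to_numpy()
    assert set(np.round(out_vals, 9)).issubset(set(np.round(vals, 9)))


def test_align_rejects_bad_interval_and_empty_input():
    with pytest.raises(DomainError):
        align_to_grid([make_series()], interval="7min")
    with pytest.raises(DomainError):
        align_to_grid([])


def test_mean_open_series_contract():
    times = pd.date_range("2019-06-01 10:00", periods=3, freq="30min")
    a = make_series("a", "open", times, [100.0, 100.0, np.nan])
    b = make_series("b", "open", times, [200.0, np.nan, np.nan])
    c = make_series("c", "canopy", times, [1.0, 1.0, 1.0])
    mean = mean_open_series([a, b, c])
    assert mean.iloc[0] == 150.0  # two sensors
    assert mean.iloc[1] == 100.0  # mean of the available one
    assert np.isnan(mean.iloc[2])  # nobody reports
    single = mean_open_series([a])
    pd.testing.assert_series_equal(single, a.data["light"], check_names=False)
    with pytest.raises(ConfigError):
        mean_open_series([c])


def test_mean_open_commutes_with_common_scaling():
    times = pd.date_range("2019-06-01 10:00", periods=5, freq="30min")
    rng = np.random.default_rng(2)
    sensors = [make_series(f"s{i}", "open", times, rng.uniform(1, 100, 5)) for i in range(3)]
    base = mean_open_series(sensors)
    scaled = [
        make_series(s.meta.sensor_id, "open", times, 3.5 * s.data["light"].to_numpy())
        for s in sensors
    ]
    pd.testing.assert_series_equal(mean_open_series(scaled), 3.5 * base)


def test_mask_windows_enumerated_half_open():
    times = pd.date_range("2019-06-01 10:00", periods=6, freq="30min")
    a = make_series("a", times=times)
    window = MaskWindow("a", times[2], times[4])
    masked, n = apply_mask_windows(a, [window])
    assert n == 2  # t2 and t3 masked, t4 (exclusive end) kept
    assert list(masked.data["light"].isna()) == [False, False, True, True, False, False]
    # idempotent
    again, n2 = apply_mask_windows(masked, [window])
    assert n2 == 0
    pd.testing.assert_frame_equal(again.data, masked.data)


def test_mask_windows_empty_and_full_and_wildcard():
    a = make_series("a")
    same, n = apply_mask_windows(a, [])
    assert n == 0
    pd.testing.assert_frame_equal(same.data, a.data)
    full = MaskWindow("*", a.data.index[0], a.data.index[-1] + pd.Timedelta(minutes=1))
    masked, n = apply_mask_windows(a, [full])
    assert n == len(a.data)
    assert masked.data["light"].isna().all()
    other = MaskWindow("b", a.data.index[0], a.data.index[-1])
    _, n = apply_mask_windows(a, [other])
    assert n == 0
    with pytest.raises(DomainError):
        MaskWindow("a", a.data.index[2], a.data.index[2])


def test_coverage_report_counts():
    times = pd.date_range("2019-06-01 10:00", periods=4, freq="30min")
    a = make_series("a", times=times, light=[1.0, np.nan, 3.0, 4.0])
    report = coverage_report([a]).iloc[0]
    assert report["n_slots"] == 4 and report["n_present"] == 3
    assert report["coverage"] == pytest.approx(0.75)
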
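"""Synthetic intertidal light-climate and deployment generator.

Forward model with known ground truth, used to validate the whole
pipeline by parameter recovery.  It composes:

* a clear-sky diel/seasonal surface light profile proportional to
  ``max(0, sin(solar elevation))``, scaled to a peak clear-sky lux,
  multiplied by an autocorrelated lognormal cloud factor (AR(1) on the
  log scale, median-preserving);
* a two-constituent tide (M2 + S2 beat) giving realistic spring-neap
  variation of the water depth above the sensors, clamped at zero when
  the shore is emersed;
* a seasonal canopy biomass trajectory
  ``T_AI(t) = mean + amplitude * cos(2*pi*(doy - peak_day)/365.25)``;
* per-sensor multiplicative lognormal noise (wave lensing on open
  sensors, sun flecks and frond movement under the canopy) -- chosen
  multiplicative and median-preserving so the log-ratio index receives
  additive, symmetric, mean-zero noise;
* a lux-sensor model with a zero floor and quantization step.

Defaults describe a year at the Galway study site: 30-minute sampling at
53.246 N, tide constituents reproducing ~1.2 m neap and ~5 m spring
ranges, 4 open + 4 canopy sensors, canopy cycle mean T_AI 4.5 with
amplitude 1.5 peaking on day 195.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ingest
from .errors import DomainError
from .solar import SiteLocation, day_of_year, solar_elevation

__all__ = [
    "LightSimConfig",
    "TideConfig",
    "CanopyConfig",
    "NoiseConfig",
    "SensorConfig",
    "SimConfig",
    "time_grid",
    "simulate_surface_light",
    "tidal_water_level",
    "simulate_tide",
    "simulate_canopy_biomass",
    "Deployment",
    "simulate_deployment",
    "simulate_reference_comparison",
]

DAYS_PER_YEAR = 365.25
M2_PERIOD_HOURS = 12.4206012
S2_PERIOD_HOURS = 12.0


@dataclass
class LightSimConfig:
    peak_lux: float = 100_000.0  # clear-sky illuminance at sin(elevation)=1
    cloud_sigma: float = 0.5  # log-scale sd of the cloud factor
    cloud_decorrelation_hours: float = 6.0


@dataclass
class TideConfig:
    mean_depth: float = 0.9  # mean water level above the sensors (m)
    m2_amplitude: float = 1.55
    s2_amplitude: float = 0.95
    m2_period_hours: float = M2_PERIOD_HOURS
    s2_period_hours: float = S2_PERIOD_HOURS
    m2_phase_rad: float = 0.0


@dataclass
class CanopyConfig:
    k_a: float = 0.7
    tai_mean: float = 4.5
    tai_amplitude: float = 1.5
    peak_day: float = 195.0  # fractional day of year of maximum biomass


@dataclass
class NoiseConfig:
    sigma_open: float = 0.5  # wave lensing etc., log scale
    sigma_canopy: float = 0.5  # sun flecks, frond movement


@dataclass
class SensorConfig:
    floor_lux: float = 1.0  # readings below this record as 0
    quantization_lux: float = 1.0  # 0 disables quantization


@dataclass
class SimConfig:
    """Full parameterization of a synthetic paired-logger deployment."""

    site: SiteLocation = field(
        default_factory=lambda: SiteLocation(latitude=53.246, longitude=-9.221, utc_offset=0.0)
    )
    start_date: str = "2019-03-01"
    n_days: int = 365
    sample_interval_min: int = 30
    water_attenuation: float = 0.4  # k_w, per metre
    light: LightSimConfig = field(default_factory=LightSimConfig)
    tide: TideConfig = field(default_factory=TideConfig)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    n_open_sensors: int = 4
    n_canopy_sensors: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if (24 * 60) % self.sample_interval_min != 0:
            raise DomainError(
                f"sample_interval_min must divide 24 h, got {self.sample_interval_min}"
            )
        for name in ("m2_amplitude", "s2_amplitude"):
            if getattr(self.tide, name) < 0:
                raise DomainError(f"tide.{name} must be >= 0")
        if self.canopy.tai_amplitude < 0:
            raise DomainError("canopy.tai_amplitude must be >= 0")
        if self.canopy.tai_mean - self.canopy.tai_amplitude < 0:
            raise DomainError(
                "canopy cycle would go negative: tai_mean - tai_amplitude < 0"
            )
        if self.n_days < 1 or self.n_open_sensors < 1 or self.n_canopy_sensors < 1:
            raise DomainError("n_days and sensor counts must be >= 1")


def time_grid(config: SimConfig) -> pd.DatetimeIndex:
    """Sampling instants of the deployment (naive local clock time)."""
    start = pd.Timestamp(config.start_date)
    n = config.n_days * (24 * 60) // config.sample_interval_min
    return pd.date_range(start, periods=n, freq=pd.Timedelta(minutes=config.sample_interval_min))


def _cloud_factor(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    sigma = config.light.cloud_sigma
    if sigma <= 0:
        return np.ones(n)
    dt_h = config.sample_interval_min / 60.0
    rho = float(np.exp(-dt_h / config.light.cloud_decorrelation_hours))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - rho**2), size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return np.exp(x)  # median-preserving: exp of a zero-mean Gaussian


def simulate_surface_light(
    config: SimConfig,
    times: pd.DatetimeIndex | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Surface illuminance: clear-sky elevation profile times a cloud factor."""
    times = time_grid(config) if times is None else times
    elev = solar_elevation(times, config.site)
    clear = config.light.peak_lux * np.clip(np.sin(np.deg2rad(elev)), 0.0, None)
    if config.light.cloud_sigma > 0:
        rng = np.random.default_rng(config.seed) if rng is None else rng
        clear = clear * _cloud_factor(config, len(times), rng)
    return pd.Series(clear, index=times, name="surface_lux")


def tidal_water_level(config: SimConfig, times: pd.DatetimeIndex | None = None) -> pd.Series:
    """Water level relative to the sensors (m), unclamped (negative = emersed)."""
    times = time_grid(config) if times is None else times
    t_h = np.asarray((times - times[0]) / pd.Timedelta(hours=1), dtype=float)
    tide = config.tide
    level = (
        tide.mean_depth
        + tide.m2_amplitude * np.cos(2 * np.pi * t_h / tide.m2_period_hours + tide.m2_phase_rad)
        + tide.s2_amplitude * np.cos(2 * np.pi * t_h / tide.s2_period_hours)
    )
    return pd.Series(level, index=times, name="water_level")


def simulate_tide(config: SimConfig, times: pd.DatetimeIndex | None = None) -> pd.Series:
    """Water depth above the sensors, clamped at 0 when the shore is emersed."""
    level = tidal_water_level(config, times)
    return pd.Series(np.clip(level.to_numpy(), 0.0, None), index=level.index, name="depth_m")


def simulate_canopy_biomass(
    config: SimConfig, times: pd.DatetimeIndex | None = None
) -> pd.Series:
    """Seasonal thallus-area-index trajectory (cosine biomass cycle)."""
    times = time_grid(config) if times is None else times
    doy = day_of_year(times, anchor_year=int(times[0].year))
    canopy = config.canopy
    tai = canopy.tai_mean + canopy.tai_amplitude * np.cos(
        2 * np.pi * (doy - canopy.peak_day) / DAYS_PER_YEAR
    )
    return pd.Series(tai, index=times, name="tai")


def _seasonal_temperature(times: pd.DatetimeIndex) -> np.ndarray:
    """Simple coastal temperature annual cycle (deg C), peaking late July."""
    doy = day_of_year(times, anchor_year=int(times[0].year))
    hour = np.asarray((times - times.normalize()) / pd.Timedelta(hours=1))
    return (
        11.5
        + 4.5 * np.cos(2 * np.pi * (doy - 209.0) / DAYS_PER_YEAR)
        + 0.6 * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    )


def _apply_sensor(values: np.ndarray, sensor: SensorConfig) -> np.ndarray:
    out = np.where(values < sensor.floor_lux, 0.0, values)
    if sensor.quantization_lux > 0:
        out = np.round(out / sensor.quantization_lux) * sensor.quantization_lux
    return out


@dataclass
class Deployment:
    """A simulated deployment: tidy logger data, sensor metadata and truth."""

    config: SimConfig
    loggers: pd.DataFrame  # timestamp, sensor_id, light_lux, temp_c
    sensors: pd.DataFrame  # sensor_id, role, patch_id, height_above_datum_m
    truth: pd.DataFrame  # timestamp, surface_lux, depth_m, tai

    def to_series(self) -> list[ingest.LoggerSeries]:
        """In-memory bridge to the ingest pipeline (no CSV round trip)."""
        meta = {
            row.sensor_id: ingest.SensorMeta(
                sensor_id=row.sensor_id,
                role=row.role,
                patch_id=row.patch_id,
                height_above_datum=row.height_above_datum_m,
            )
            for row in self.sensors.itertuples()
        }
        tidy = self.loggers.rename(columns={"light_lux": "light", "temp_c": "temperature"})
        return ingest.series_from_tidy(tidy, metadata=meta)

    def write(self, outdir) -> dict[str, Path]:
        """Write loggers.csv, sensors.csv, truth.csv and a config echo YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "loggers": outdir / "loggers.csv",
            "sensors": outdir / "sensors.csv",
            "truth": outdir / "truth.csv",
            "config": outdir / "config.yaml",
        }
        self.loggers.to_csv(paths["loggers"], index=False, date_format="%Y-%m-%dT%H:%M:%S")
        self.sensors.to_csv(paths["sensors"], index=False)
        self.truth.to_csv(paths["truth"], index=False, date_format="%Y-%m-%dT%H:%M:%S")
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=False)
        return paths


def simulate_deployment(config: SimConfig | None = None) -> Deployment:
    """Generate a full paired-logger deployment with ground truth.

    Open sensors record ``I_s exp(-k_w z)`` and canopy sensors
    ``I_s exp(-k_w z - k_a T_AI(t))``, each multiplied by its own
    lognormal noise, floored and quantized.  Fully reproducible from
    ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    times = time_grid(config)
    surface = simulate_surface_light(config, times, rng).to_numpy()
    depth = simulate_tide(config, times).to_numpy()
    tai = simulate_canopy_biomass(config, times).to_numpy()
    water_term = np.exp(-config.water_attenuation * depth)
    open_bed = surface * water_term
    canopy_bed = open_bed * np.exp(-config.canopy.k_a * tai)
    temp = _seasonal_temperature(times)

    frames = []
    sensor_rows = []

    def add_sensor(sensor_id, role, patch_id, base, sigma):
        noise = np.exp(rng.normal(0.0, sigma, size=len(times))) if sigma > 0 else 1.0
        light = _apply_sensor(base * noise, config.sensor)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": times,
                    "sensor_id": sensor_id,
                    "light_lux": light,
                    "temp_c": np.round(temp, 2),
                }
            )
        )
        sensor_rows.append(
            {
                "sensor_id": sensor_id,
                "role": role,
                "patch_id": patch_id,
                "height_above_datum_m": 1.8,
            }
        )

    for i in range(config.n_open_sensors):
        add_sensor(f"open-{i + 1}", "open", f"O{i % 2 + 1}", open_bed, config.noise.sigma_open)
    for i in range(config.n_canopy_sensors):
        add_sensor(
            f"canopy-{i + 1}", "canopy", f"C{i % 2 + 1}", canopy_bed, config.noise.sigma_canopy
        )

    loggers = pd.concat(frames, ignore_index=True)
    sensors = pd.DataFrame(sensor_rows)
    truth = pd.DataFrame(
        {"timestamp": times, "surface_lux": surface, "depth_m": depth, "tai": tai}
    )
    return Deployment(config=config, loggers=loggers, sensors=sensors, truth=truth)


def simulate_reference_comparison(
    n_days: int = 365,
    start_date: str = "2019-03-01",
    site: SiteLocation | None = None,
    cloud_sigma: float = 0.5,
    sensor_sigma: float = 0.05,
    decay_per_year: float = 0.0,
    scale: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily logger-vs-reference intercomparison with optional sensitivity decay.

    Emulates the drift check against a nearby reference radiation record:
    both the reference and the logger see the same simulated sky (daily
    clear-sky mean times an independent lognormal cloud factor per day);
    the logger additionally carries a proportionality constant ``scale``,
    small independent lognormal measurement noise ``sensor_sigma`` (small
    because daily means average ~100 half-hourly readings over several
    sensors) and, when ``decay_per_year > 0``, a linear loss of
    sensitivity with time.  Returns a frame indexed by date with
    ``reference`` and ``logger`` columns.
    """
    site = site or SiteLocation(latitude=53.246, longitude=-9.221)
    rng = np.random.default_rng(seed)
    days = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    # clear-sky daily mean illuminance from half-hourly solar elevation
    half_hours = pd.date_range(days[0], periods=n_days * 48, freq="30min")
    elev = solar_elevation(half_hours, site)
    clear = np.clip(np.sin(np.deg2rad(elev)), 0.0, None).reshape(n_days, 48).mean(axis=1)
    cloud = np.exp(rng.normal(0.0, cloud_sigma, size=n_days)) if cloud_sigma > 0 else 1.0
    reference = clear * cloud
    sensitivity = np.clip(1.0 - decay_per_year * np.arange(n_days) / DAYS_PER_YEAR, 0.0, None)
    meas = np.exp(rng.normal(0.0, sensor_sigma, size=n_days)) if sensor_sigma > 0 else 1.0
    logger_vals = scale * reference * sensitivity * meas
    return pd.DataFrame({"reference": reference, "logger": logger_vals}, index=days)
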
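"""Seasonal trend extraction from the attenuation-index series.

The half-hourly index is noisy (wave lensing, sun flecks, frond
movement), but canopy biomass changes gradually, so the seasonal signal
is extracted with a LOESS smoother: at each evaluation point a
polynomial (degree 1 by default) is fitted by weighted least squares to
the ``ceil(span * n)`` nearest neighbours, with tricube weights and
optional bisquare robustness iterations.  A span of 0.4 suits a
year-long deployment.  Seasonal extrema of the smoothed curves are then
summarised across sensors, and :func:`drift_check` implements the
sensor-stability test (regression of logger daily means against a
reference radiation series; trend in the residuals indicates drift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "loess_smooth",
    "Extrema",
    "extract_extrema",
    "TrendSummary",
    "summarize_sensors",
    "DriftReport",
    "drift_check",
]


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _fit_point(
    x0: float,
    x: np.ndarray,
    y: np.ndarray,
    q: int,
    degree: int,
    robust_w: np.ndarray,
) -> float:
    d = np.abs(x - x0)
    dmax = np.partition(d, q - 1)[q - 1] if q < len(x) else d.max()
    if dmax <= 0:
        # all neighbours coincide with x0: weighted mean of the stacked points
        at = d == 0
        w = robust_w[at]
        return float(np.average(y[at], weights=w) if w.sum() > 0 else y[at].mean())
    w = _tricube(d / dmax) * robust_w
    sw = w.sum()
    if sw <= 0:
        return float("nan")
    xc = x - x0
    if degree == 1:
        swx = np.dot(w, xc)
        swy = np.dot(w, y)
        swxx = np.dot(w, xc * xc)
        swxy = np.dot(w, xc * y)
        denom = swxx - swx * swx / sw
        if denom <= 1e-12 * max(swxx, 1e-300):
            return float(swy / sw)
        slope = (swxy - swx * swy / sw) / denom
        return float((swy - slope * swx) / sw)
    basis = np.vander(xc, degree + 1, increasing=True)
    sw_sqrt = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(basis * sw_sqrt[:, None], y * sw_sqrt, rcond=None)
    return float(coef[0])


def loess_smooth(
    x,
    y,
    span: float = 0.4,
    degree: int = 1,
    robustness: int = 0,
    eval_x=None,
) -> np.ndarray:
    """Locally weighted polynomial smoother (LOESS).

    Parameters
    ----------
    x, y
        Observation positions (e.g. fractional day of year) and values.
        Missing (NaN) ``y`` are excluded before fitting; fitted values
        are still returned at every requested position.
    span
        Fraction of the *present* points used in each local fit,
        in (0, 1].
    degree
        Local polynomial degree, 1 or 2.
    robustness
        Number of bisquare robustness iterations (0 = plain fit).
    eval_x
        Positions at which to evaluate the smooth; defaults to ``x``.

    Returns
    -------
    ndarray of fitted values at ``eval_x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have the same shape")
    if degree not in (1, 2):
        raise DomainError(f"degree must be 1 or 2, got {degree!r}")
    if not 0 < span <= 1:
        raise DomainError(f"span must be in (0, 1], got {span!r}")
    if robustness < 0:
        raise DomainError("robustness must be >= 0")
    present = np.isfinite(x) & np.isfinite(y)
    xt, yt = x[present], y[present]
    n = len(xt)
    if n < max(degree + 2, 10):
        raise DomainError(
            f"loess_smooth needs at least {max(degree + 2, 10)} present points, got {n}"
        )
    q = min(max(int(math.ceil(span * n)), degree + 1), n)
    robust_w = np.ones(n)
    for _ in range(robustness):
        fitted = np.array([_fit_point(x0, xt, yt, q, degree, robust_w) for x0 in xt])
        resid = yt - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    targets = xt if eval_x is None else np.asarray(eval_x, dtype=float)
    out = np.array([_fit_point(x0, xt, yt, q, degree, robust_w) for x0 in targets])
    if eval_x is None:
        # map back onto the full input layout, NaN where y was missing
        full = np.full(x.shape, np.nan)
        full[present] = out
        return full
    return out


@dataclass(frozen=True)
class Extrema:
    """Seasonal extrema of one sensor's smoothed index curve."""

    peak_value: float
    peak_day: float
    trough_value: float
    trough_day: float


def extract_extrema(day_of_year, values) -> Extrema:
    """Peak and trough of a smoothed series; ties broken by earliest day."""
    day = np.asarray(day_of_year, dtype=float)
    vals = np.asarray(values, dtype=float)
    present = np.isfinite(day) & np.isfinite(vals)
    if not present.any():
        raise DomainError("extract_extrema: no finite values")
    day, vals = day[present], vals[present]
    order = np.argsort(day, kind="stable")
    day, vals = day[order], vals[order]
    i_max = int(np.argmax(vals))  # argmax/argmin return the first (earliest) tie
    i_min = int(np.argmin(vals))
    return Extrema(
        peak_value=float(vals[i_max]),
        peak_day=float(day[i_max]),
        trough_value=float(vals[i_min]),
        trough_day=float(day[i_min]),
    )


@dataclass(frozen=True)
class TrendSummary:
    """Cross-sensor mean and standard error of the seasonal extrema.

    SE is the sample (n-1) standard deviation over sensors divided by
    sqrt(n); NaN with a single sensor.
    """

    n_sensors: int
    peak_value_mean: float
    peak_value_se: float
    peak_day_mean: float
    peak_day_se: float
    trough_value_mean: float
    trough_value_se: float
    trough_day_mean: float
    trough_day_se: float

    def as_dict(self) -> dict:
        return {
            "n_sensors": self.n_sensors,
            "peak_value": {"mean": self.peak_value_mean, "se": self.peak_value_se},
            "peak_day": {"mean": self.peak_day_mean, "se": self.peak_day_se},
            "trough_value": {"mean": self.trough_value_mean, "se": self.trough_value_se},
            "trough_day": {"mean": self.trough_day_mean, "se": self.trough_day_se},
        }


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 1:
        return float(values[0]), float("nan")
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(len(values)))


def summarize_sensors(extrema_list) -> TrendSummary:
    """Aggregate per-sensor :class:`Extrema` into a :class:`TrendSummary`."""
    extrema_list = list(extrema_list)
    if not extrema_list:
        raise DomainError("summarize_sensors: empty extrema list")
    cols = {
        name: np.array([getattr(e, name) for e in extrema_list], dtype=float)
        for name in ("peak_value", "peak_day", "trough_value", "trough_day")
    }
    stats_ = {name: _mean_se(v) for name, v in cols.items()}
    return TrendSummary(
        n_sensors=len(extrema_list),
        peak_value_mean=stats_["peak_value"][0],
        peak_value_se=stats_["peak_value"][1],
        peak_day_mean=stats_["peak_day"][0],
        peak_day_se=stats_["peak_day"][1],
        trough_value_mean=stats_["trough_value"][0],
        trough_value_se=stats_["trough_value"][1],
        trough_day_mean=stats_["trough_day"][0],
        trough_day_se=stats_["trough_day"][1],
    )


@dataclass(frozen=True)
class DriftReport:
    """Sensor stability check against an independent daily reference.

    ``r_squared`` measures how well logger daily means track the
    reference; ``residual_date_r_squared`` close to 0 indicates no
    sensitivity drift over the deployment, values well above 0 a
    time-dependent bias.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_date_r_squared: float
    n_days: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "residual_date_r_squared": self.residual_date_r_squared,
            "n_days": self.n_days,
        }


def drift_check(logger_daily: pd.Series, reference_daily: pd.Series) -> DriftReport:
    """OLS of logger daily means on a reference series, then residual-vs-date fit.

    Both inputs are daily series indexed by date; only shared dates with
    both values present are used (at least 10 required).
    """
    paired = pd.DataFrame({"logger": logger_daily, "reference": reference_daily}).dropna()
    if len(paired) < 10:
        raise DomainError(f"drift_check needs >= 10 paired days, got {len(paired)}")
    fit = stats.linregress(paired["reference"], paired["logger"])
    residuals = paired["logger"] - (fit.intercept + fit.slope * paired["reference"])
    dates = pd.DatetimeIndex(paired.index)
    day_num = (dates - dates[0]) / pd.Timedelta(days=1)
    if np.std(residuals.to_numpy()) <= 1e-12 * max(1.0, float(np.abs(paired["logger"]).max())):
        resid_r2 = 0.0  # exact fit: no residual structure, hence no drift signal
    else:
        resid_fit = stats.linregress(np.asarray(day_num, dtype=float), residuals)
        resid_r2 = float(resid_fit.rvalue**2)
    return DriftReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_date_r_squared=resid_r2,
        n_days=len(paired),
    )
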
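"""Beer-Lambert model of seabed light under and outside a macroalgal canopy.

The biomass proxy is built from two sensors in the same body of water: one
under 100% canopy cover (reading ``I_c``) and one on open rock (``I_o``).
Light reaching the seabed is attenuated by the water column (coefficient
``k_w`` per metre over depth ``z``) and, under the canopy, additionally by
the algal fronds (coefficient ``k_a`` per unit of thallus area index
``T_AI``, the m^2 of frond per m^2 of seabed):

    I_c = I_s * exp(-k_w * z - k_a * T_AI)
    I_o = I_s * exp(-k_w * z)

Because both sensors share ``I_s``, ``k_w`` and ``z``, the log-ratio

    ln(I_o / I_c) = k_a * T_AI

depends only on the canopy.  This quantity is the *attenuation index* (the
"T_AI index"): a dimensionless biomass proxy that is invariant to surface
light, water depth and turbidity, and to the sensor's intensity unit.  If
``k_a`` is known the index converts directly to thallus area index, and via
a specific thallus area to biomass.

All functions accept scalars or numpy arrays and are unit-agnostic (lux by
default); the index is a pure ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "LightEnvironment",
    "CanopyState",
    "CalibrationParams",
    "seabed_light_under_canopy",
    "seabed_light_open",
    "attenuation_index",
    "index_to_tai",
    "tai_to_index",
    "wet_weight_to_tai",
]

#: Mid-range canopy attenuation coefficient for fucoids (per unit T_AI).
DEFAULT_K_A = 0.7

#: Fraction of fucoid wet weight that is water.
DEFAULT_WATER_CONTENT = 0.784


def _require_nonnegative_finite(**values: float) -> None:
    for name, value in values.items():
        if not np.all(np.isfinite(value)):
            raise DomainError(f"{name} must be finite, got {value!r}")
        if np.any(np.asarray(value) < 0):
            raise DomainError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class LightEnvironment:
    """Ambient light field shared by a paired-sensor deployment.

    Parameters
    ----------
    surface_light
        Light intensity just above the water surface (lux or any
        consistent unit), >= 0.
    water_attenuation
        Diffuse attenuation coefficient of the water column ``k_w``
        (per metre), >= 0.
    depth
        Water depth above the sensors ``z`` (metres), >= 0.  Zero means
        the sensors are at or above the water line and the water term
        vanishes.
    """

    surface_light: float
    water_attenuation: float
    depth: float

    def __post_init__(self) -> None:
        _require_nonnegative_finite(
            surface_light=self.surface_light,
            water_attenuation=self.water_attenuation,
            depth=self.depth,
        )


@dataclass(frozen=True)
class CanopyState:
    """Canopy above the under-canopy sensor.

    ``thallus_area_index`` may exceed 1 for multilayered canopies.
    """

    thallus_area_index: float
    canopy_attenuation: float = DEFAULT_K_A

    def __post_init__(self) -> None:
        _require_nonnegative_finite(
            thallus_area_index=self.thallus_area_index,
            canopy_attenuation=self.canopy_attenuation,
        )


@dataclass(frozen=True)
class CalibrationParams:
    """Parameters converting the attenuation index to thallus area and biomass.

    Parameters
    ----------
    canopy_attenuation
        ``k_a`` per unit T_AI; must be > 0 when used for index -> T_AI
        conversion.  0.7 is a mid-range literature value for fucoids.
    water_content
        Fraction of wet weight that is water, in [0, 1).
    specific_thallus_area
        m^2 of thallus per g dry weight, > 0.  Species specific; the
        defaults offered in :mod:`canopylux.simulate` docs are
        reconstructions back-solved from published shore means, not
        measured constants.
    """

    canopy_attenuation: float = DEFAULT_K_A
    water_content: float = DEFAULT_WATER_CONTENT
    specific_thallus_area: float = 0.0082

    def __post_init__(self) -> None:
        if not (0 <= self.water_content < 1):
            raise DomainError(
                f"water_content must be in [0, 1), got {self.water_content!r}"
            )
        if not (self.specific_thallus_area > 0 and math.isfinite(self.specific_thallus_area)):
            raise DomainError(
                "specific_thallus_area must be > 0, got "
                f"{self.specific_thallus_area!r}"
            )
        _require_nonnegative_finite(canopy_attenuation=self.canopy_attenuation)


def seabed_light_under_canopy(env: LightEnvironment, canopy: CanopyState):
    """Light reaching the seabed below a canopy: ``I_s exp(-k_w z - k_a T_AI)``."""
    return env.surface_light * np.exp(
        -env.water_attenuation * env.depth
        - canopy.canopy_attenuation * canopy.thallus_area_index
    )


def seabed_light_open(env: LightEnvironment):
    """Light reaching open (canopy-free) seabed: ``I_s exp(-k_w z)``."""
    return env.surface_light * np.exp(-env.water_attenuation * env.depth)


def attenuation_index(i_open, i_canopy, threshold: float = 0.0):
    """Canopy attenuation index ``ln(I_o / I_c)``.

    Values where either sensor reading is missing or ``<= threshold``
    (default 0, i.e. strict positivity required of both) are returned as
    NaN rather than raising: darkness makes the log-ratio undefined, and
    a zero open reading with a positive canopy reading would make it
    infinite.  The threshold can be raised for sensors with a noise
    floor.  Slightly negative indices (canopy sensor brighter than the
    open mean, possible in noisy data) are retained, not clipped, so
    downstream smoothing stays unbiased.

    Scalar inputs return a scalar float; array inputs an ndarray.
    """
    i_o = np.asarray(i_open, dtype=float)
    i_c = np.asarray(i_canopy, dtype=float)
    valid = np.isfinite(i_o) & np.isfinite(i_c) & (i_o > threshold) & (i_c > threshold)
    out = np.full(np.broadcast(i_o, i_c).shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.log(np.broadcast_to(i_o, out.shape) / np.broadcast_to(i_c, out.shape),
               out=out, where=valid)
    out[~valid] = np.nan
    if out.ndim == 0:
        return float(out)
    return out


def index_to_tai(index, k_a: float = DEFAULT_K_A):
    """Convert the attenuation index to thallus area index: ``index / k_a``."""
    if not (k_a > 0 and math.isfinite(k_a)):
        raise DomainError(f"k_a must be > 0 for index -> T_AI conversion, got {k_a!r}")
    return np.asarray(index, dtype=float) / k_a if np.ndim(index) else float(index) / k_a


def tai_to_index(tai, k_a: float = DEFAULT_K_A):
    """Inverse of :func:`index_to_tai`: ``k_a * T_AI``."""
    _require_nonnegative_finite(k_a=k_a)
    return k_a * np.asarray(tai, dtype=float) if np.ndim(tai) else k_a * float(tai)


def wet_weight_to_tai(wet_weight, cal: CalibrationParams):
    """Thallus area index implied by a harvested wet weight (g m^-2).

    ``T_AI = wet_weight * (1 - water_content) * specific_thallus_area``.
    Linear in wet weight; used to cross-reference the optical proxy
    against destructive quadrat harvests.
    """
    _require_nonnegative_finite(wet_weight=wet_weight)
    scale = (1.0 - cal.water_content) * cal.specific_thallus_area
    if np.ndim(wet_weight):
        return np.asarray(wet_weight, dtype=float) * scale
    return float(wet_weight) * scale
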
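"""FAO-56 Penman–Monteith reference evapotranspiration.

Daily reference evapotranspiration of a standard grass surface:

    ET0 = [0.408·Δ·(Rn − G) + γ·(900/(T+273))·u2·(es − ea)]
          / [Δ + γ·(1 + 0.34·u2)]                       (mm d⁻¹)

with net radiation Rn and soil heat flux G in MJ m⁻² d⁻¹, mean air
temperature T in °C, wind speed u2 at 2 m in m s⁻¹, saturation and actual
vapour pressure es, ea in kPa, saturation-vapour-pressure slope Δ and
psychrometric constant γ in kPa °C⁻¹.  The auxiliary formulas for Δ, γ, es
and ea follow the FAO-56 standard.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WeatherDay",
    "saturation_vapour_pressure",
    "svp_slope",
    "atmospheric_pressure",
    "psychrometric_constant",
    "penman_monteith",
    "seasonal_mean_et0",
]

#: Station altitude (m) used for the default psychrometric constant.
DEFAULT_ALTITUDE_M = 81.0


def saturation_vapour_pressure(T_celsius: float) -> float:
    """es(T) in kPa (FAO-56 Eq. for saturation vapour pressure)."""
    return 0.6108 * np.exp(17.27 * T_celsius / (T_celsius + 237.3))


def svp_slope(T_celsius: float) -> float:
    """Δ, the slope of the saturation-vapour-pressure curve (kPa °C⁻¹)."""
    return 4098.0 * saturation_vapour_pressure(T_celsius) / (T_celsius + 237.3) ** 2


def atmospheric_pressure(altitude_m: float) -> float:
    """Barometric pressure (kPa) from altitude."""
    return 101.3 * ((293.0 - 0.0065 * altitude_m) / 293.0) ** 5.26


def psychrometric_constant(altitude_m: float = DEFAULT_ALTITUDE_M) -> float:
    """γ (kPa °C⁻¹) from station pressure."""
    return 0.665e-3 * atmospheric_pressure(altitude_m)


@dataclass(frozen=True)
class WeatherDay:
    """One day of the meteorological inputs the reference-ET formula needs.

    ``es``/``ea`` may be given directly or derived from ``T_mean`` and
    ``RH_mean_pct`` via :meth:`from_relative_humidity`.
    """

    date: _dt.date
    Rn: float  # net radiation, MJ m-2 d-1
    G: float  # soil heat flux, MJ m-2 d-1
    T_mean: float  # deg C
    u2: float  # wind speed at 2 m, m s-1
    es: float  # saturation vapour pressure, kPa
    ea: float  # actual vapour pressure, kPa
    altitude_m: float = DEFAULT_ALTITUDE_M

    def __post_init__(self) -> None:
        if self.u2 < 0:
            raise ValueError("u2 must be >= 0")
        if self.es <= 0 or self.ea < 0:
            raise ValueError("vapour pressures must be positive (es) / non-negative (ea)")
        if self.ea > self.es + 1e-12:
            raise ValueError(f"ea={self.ea} kPa exceeds es={self.es} kPa")

    @classmethod
    def from_relative_humidity(
        cls,
        date: _dt.date,
        Rn: float,
        G: float,
        T_mean: float,
        u2: float,
        RH_mean_pct: float,
        altitude_m: float = DEFAULT_ALTITUDE_M,
    ) -> "WeatherDay":
        if not 0 <= RH_mean_pct <= 100:
            raise ValueError("RH_mean_pct must be in [0, 100]")
        es = float(saturation_vapour_pressure(T_mean))
        return cls(date, Rn, G, T_mean, u2, es=es, ea=RH_mean_pct / 100.0 * es,
                   altitude_m=altitude_m)


def penman_monteith(day: WeatherDay) -> float:
    """Daily reference evapotranspiration ET0 (mm d⁻¹), clamped at 0."""
    delta = svp_slope(day.T_mean)
    gamma = psychrometric_constant(day.altitude_m)
    num = 0.408 * delta * (day.Rn - day.G) + gamma * (900.0 / (day.T_mean + 273.0)) * day.u2 * (
        day.es - day.ea
    )
    den = delta + gamma * (1.0 + 0.34 * day.u2)
    et0 = num / den
    if et0 < 0:
        warnings.warn(
            f"negative ET0 ({et0:.3f} mm/d) on {day.date}: clamped to 0", RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(et0)


def seasonal_mean_et0(days: Sequence[WeatherDay]) -> float:
    """Arithmetic mean of daily ET0 over a season (mm d⁻¹)."""
    if not days:
        raise ValueError("need at least one weather day")
    return float(np.mean([penman_monteith(d) for d in days]))
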
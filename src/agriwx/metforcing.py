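"""Meteorological forcing: solar geometry, sunshine-to-radiation conversion and
FAO-56 Penman-Monteith reference evapotranspiration.

All functions are elementwise numpy ufunc compositions and accept scalars or
arrays. Units follow the FAO-56 conventions: radiation in MJ m-2 day-1,
temperature in degrees Celsius, evapotranspiration in mm day-1, day of year in
1..365 (the package uses a 365-day calendar throughout).

The reference-surface assumptions of FAO-56 apply: a well-watered clipped grass
sward, daily time step, soil heat flux G = 0. Wind speed and humidity are not
observed inputs in this pipeline; the FAO-56 fallbacks are used (fixed 2 m
wind, dew point approximated by the daily minimum temperature, appropriate for
a humid temperate climate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SOLAR_CONSTANT",
    "extraterrestrial_radiation",
    "daylength",
    "sunshine_to_radiation",
    "penman_monteith_et0",
    "ET0Day",
]

#: Solar constant, MJ m-2 min-1 (FAO-56 value).
SOLAR_CONSTANT = 0.0820

#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1.
STEFAN_BOLTZMANN = 4.903e-9

#: Grass reference albedo.
ALBEDO = 0.23

#: Latitude poleward of which the sunset-hour-angle formula degenerates
#: (polar day/night); outside the study area by a wide margin.
MAX_ABS_LATITUDE = 66.5


def _solar_declination(doy):
    return 0.409 * np.sin(2.0 * np.pi * np.asarray(doy) / 365.0 - 1.39)


def _inverse_relative_distance(doy):
    return 1.0 + 0.033 * np.cos(2.0 * np.pi * np.asarray(doy) / 365.0)


def extraterrestrial_radiation(latitude, doy):
    """Daily extraterrestrial radiation Ra and astronomical daylength N.

    Parameters
    ----------
    latitude : float or array
        Site latitude in decimal degrees, ``|latitude| < 66.5``.
    doy : int or array
        Day of year, 1..365.

    Returns
    -------
    (Ra, N)
        Ra in MJ m-2 day-1 and daylength N in hours.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) >= MAX_ABS_LATITUDE):
        raise ValueError(
            f"latitude must satisfy |lat| < {MAX_ABS_LATITUDE} deg; got {latitude!r}"
        )
    phi = np.deg2rad(lat)
    delta = _solar_declination(doy)
    dr = _inverse_relative_distance(doy)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    n = 24.0 / np.pi * ws
    return ra, n


def daylength(latitude, doy):
    """Astronomical daylength in hours (convenience wrapper)."""
    return extraterrestrial_radiation(latitude, doy)[1]


def sunshine_to_radiation(sun_hours, ra, n, a=0.25, b=0.50):
    """Angstrom-Prescott conversion of bright sunshine hours to global radiation.

    Rs = (a + b * n_sun / N) * Ra.  The coefficients default to the FAO-56
    recommendations for sites without a local calibration.  Sunshine durations
    exceeding the astronomical daylength are clamped with a warning.
    """
    if not (a > 0 and b > 0):
        raise ValueError("Angstrom coefficients a, b must be positive")
    sun = np.asarray(sun_hours, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(sun > n + 1e-9):
        warnings.warn(
            "sunshine hours exceed daylength on some days; clamping to daylength",
            stacklevel=2,
        )
    sun = np.clip(sun, 0.0, n)
    frac = np.divide(sun, n, out=np.zeros_like(sun), where=n > 0)
    return (a + b * frac) * np.asarray(ra, dtype=float)


def _saturation_vapour_pressure(t):
    """Tetens saturation vapour pressure, kPa, t in degC."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


@dataclass(frozen=True)
class ET0Day:
    """Reference evapotranspiration with the inputs echoed for traceability."""

    et0: float
    tmax: float
    tmin: float
    rs: float
    wind_speed: float
    ea: float


def penman_monteith_et0(
    tmax,
    tmin,
    rs,
    latitude,
    doy,
    elevation=50.0,
    wind_speed=2.0,
):
    """Daily FAO-56 Penman-Monteith reference evapotranspiration (mm day-1).

    Humidity is estimated from the minimum temperature (dew point ~ tmin, a
    standard fallback for humid climates) and wind speed defaults to 2 m s-1.
    Accepts scalars or equally shaped arrays; returns an array (or scalar) of
    non-negative ET0 values.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    rs = np.asarray(rs, dtype=float)
    if np.any(tmax < tmin - 1e-9):
        raise ValueError("tmax must be >= tmin")

    tmean = (tmax + tmin) / 2.0
    # Psychrometric constant from elevation-adjusted pressure.
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    delta = 4098.0 * _saturation_vapour_pressure(tmean) / (tmean + 237.3) ** 2

    es = (_saturation_vapour_pressure(tmax) + _saturation_vapour_pressure(tmin)) / 2.0
    ea = _saturation_vapour_pressure(tmin)  # dew point ~ tmin

    ra, _ = extraterrestrial_radiation(latitude, doy)
    rso = (0.75 + 2e-5 * elevation) * ra
    rel = np.divide(rs, rso, out=np.ones_like(rs), where=rso > 0)
    rel = np.clip(rel, 0.0, 1.0)
    rns = (1.0 - ALBEDO) * rs
    tk4 = ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
    rnl = (
        STEFAN_BOLTZMANN
        * tk4
        * (0.34 - 0.14 * np.sqrt(ea))
        * (1.35 * rel - 0.35)
    )
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * wind_speed * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * wind_speed)
    et0 = np.maximum(num / den, 0.0)
    if et0.ndim == 0:
        return float(et0)
    return et0
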
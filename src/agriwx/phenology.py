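"""Winter wheat phenology by thermal time.

Development is driven solely by accumulated thermal time (daily mean
temperature above a base temperature, degC day): each stage is reached on the
first day the cumulative sum from sowing meets that stage's target.  No
vernalisation or photoperiod response is modelled; the default targets are
calibrated so that a 20 October sowing under the package's temperate-maritime
baseline flowers in mid June and matures in early August, and they are plain
configuration for other climates or cultivars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CultivarParams",
    "PhenoDates",
    "CropFailureError",
    "daily_thermal_time",
    "predict_stages",
    "SOWING_DOY_DEFAULT",
]

#: 20 October in the 365-day calendar.
SOWING_DOY_DEFAULT = 293


@dataclass(frozen=True)
class CultivarParams:
    """Thermal-time targets (degC day) for a medium-ripening winter wheat."""

    base_temperature: float = 0.0
    tt_sowing_to_emergence: float = 150.0
    tt_emergence_to_anthesis: float = 1700.0
    tt_anthesis_to_maturity: float = 900.0
    label: str = "medium-ripening"

    def __post_init__(self):
        for name in ("tt_sowing_to_emergence", "tt_emergence_to_anthesis",
                     "tt_anthesis_to_maturity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class CropFailureError(RuntimeError):
    """Maturity was not reached before the end of the season window."""


@dataclass(frozen=True)
class PhenoDates:
    """Stage indices (into the season slice) and diagnostics for one season.

    ``*_idx`` are offsets in days from the start of the supplied slice;
    ``*_doy`` are days of year in the 365-day calendar.  The temperature rates
    are accumulated thermal time divided by elapsed days for the two phases
    the diagnostics report (sowing-anthesis and anthesis-maturity).
    """

    sowing_idx: int
    emergence_idx: int
    anthesis_idx: int
    maturity_idx: int
    sowing_doy: int
    emergence_doy: int
    anthesis_doy: int
    maturity_doy: int
    temperature_rate_sowing_anthesis: float
    temperature_rate_anthesis_maturity: float

    def __post_init__(self):
        if not (self.sowing_idx < self.emergence_idx
                < self.anthesis_idx < self.maturity_idx):
            raise ValueError("stage ordering violated")


def daily_thermal_time(tmax, tmin, base: float = 0.0):
    """Thermal time for one day: max(0, (tmax + tmin)/2 - base), degC day."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin - 1e-9):
        raise ValueError("tmax must be >= tmin")
    tt = np.maximum(0.0, (tmax + tmin) / 2.0 - base)
    if tt.ndim == 0:
        return float(tt)
    return tt


def predict_stages(
    tmax: np.ndarray,
    tmin: np.ndarray,
    sowing_idx: int,
    sowing_doy: int,
    cultivar: CultivarParams = CultivarParams(),
) -> PhenoDates:
    """Predict emergence, anthesis and maturity for one crop season.

    ``tmax``/``tmin`` are daily arrays for a slice that contains the sowing
    day and extends through the following summer.  Raises
    :class:`CropFailureError` if the maturity target is not met before the
    slice ends (callers exclude such years with a warning).
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    n = len(tmax)
    if not 0 <= sowing_idx < n - 1:
        raise ValueError("sowing_idx outside the season slice")

    # Accumulation starts the day after sowing.
    tt = daily_thermal_time(tmax[sowing_idx + 1:], tmin[sowing_idx + 1:],
                            cultivar.base_temperature)
    cum = np.cumsum(tt)
    targets = np.cumsum([
        cultivar.tt_sowing_to_emergence,
        cultivar.tt_emergence_to_anthesis,
        cultivar.tt_anthesis_to_maturity,
    ])
    # First day (offset from sowing) on which each cumulative target is met.
    idx = np.searchsorted(cum, targets, side="left")
    if idx[2] >= len(cum):
        raise CropFailureError(
            "maturity not reached before the end of the season window"
        )
    # Guarantee strict stage ordering even for degenerate targets.
    for k in (1, 2):
        if idx[k] <= idx[k - 1]:
            idx[k] = idx[k - 1] + 1
    if idx[2] >= len(cum):
        raise CropFailureError("season window too short after ordering repair")
    emergence, anthesis, maturity = (int(i) + 1 + sowing_idx for i in idx)

    def _doy(i):
        return (sowing_doy - 1 + (i - sowing_idx)) % 365 + 1

    days_sa = anthesis - sowing_idx
    days_am = maturity - anthesis
    tt_sa = float(cum[idx[1]])
    tt_am = float(cum[idx[2]] - cum[idx[1]])
    return PhenoDates(
        sowing_idx=sowing_idx,
        emergence_idx=emergence,
        anthesis_idx=anthesis,
        maturity_idx=maturity,
        sowing_doy=sowing_doy,
        emergence_doy=_doy(emergence),
        anthesis_doy=_doy(anthesis),
        maturity_doy=_doy(maturity),
        temperature_rate_sowing_anthesis=tt_sa / days_sa,
        temperature_rate_anthesis_maturity=tt_am / days_am,
    )
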
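"""Adverse-weather event detectors for winter wheat and their probabilities.

Seven binary events are evaluated on each crop season (sowing to maturity,
with margins for the sowing and harvest windows):

1. frost with no snow   -- tmin <= -20 degC on a day with < 1 cm snow cover;
2. late frost           -- tmin <= -2 degC after winter hardiness is lost
   (mean temperature >= 10 degC for >= 5 consecutive days, regained only if
   it then drops below 10 degC for more than 2 days in a row);
3. extremely wet early season -- more than 60 days (cumulative) between
   sowing and anthesis with the soil at or above field capacity, days with
   mean temperature < 3 degC not counted;
4. lodging risk         -- at least 2 days between anthesis and 5 days before
   maturity with precipitation > 40 mm, or > 20 mm on a day following a day
   at or above field capacity;
5. grain-filling heat   -- tmax > 35 degC on at least 3 days (cumulative)
   from 5 days after anthesis to maturity;
6. adverse sowing conditions  -- fewer than 3 workable days in the 31-day
   window centred on sowing (workable: top-layer saturation strictly between
   5% and 90%, rain < 5 mm that day and <= 10 mm the day before);
7. adverse harvest conditions -- fewer than 3 workable days in the window
   maturity+5 .. maturity+25 (workable: top-layer saturation < 85%, rain
   < 0.5 mm that day and <= 5 mm the day before).

Counting thresholds are cumulative, not consecutive, except where the late
frost trigger itself demands a run of days.  The per-season flags are
aggregated into occurrence probabilities over the retained (post-spin-up)
years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phenology import PhenoDates

__all__ = [
    "CropYear",
    "EventFlags",
    "EVENT_NAMES",
    "detect_frost_no_snow",
    "detect_late_frost",
    "detect_wet_early_season",
    "detect_lodging_risk",
    "detect_grainfill_heat",
    "detect_adverse_sowing",
    "detect_adverse_harvest",
    "detect_all",
    "event_probability",
]

EVENT_NAMES = (
    "frost_no_snow",
    "late_frost",
    "wet_early_season",
    "lodging_risk",
    "grainfill_heat",
    "adverse_sowing",
    "adverse_harvest",
)

#: Snow depth (cm) below which cover counts as "no or very limited snow".
SNOW_COVER_LIMIT_CM = 1.0


@dataclass
class CropYear:
    """One season's forcing and soil state, plus the phenology dates.

    All arrays share one daily index; ``pheno`` indices point into them.  The
    slice must start at least 16 days before sowing and extend at least 25
    days past maturity so the sowing and harvest windows (including the
    preceding-day rain condition) are in range.
    """

    harvest_year: int
    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray
    at_fc: np.ndarray               # profile at/above field capacity, bool
    top_saturation: np.ndarray      # top-layer relative saturation, 0..1+
    snow_depth_cm: np.ndarray
    pheno: PhenoDates

    @property
    def tmean(self) -> np.ndarray:
        return (self.tmax + self.tmin) / 2.0

    def __post_init__(self):
        n = len(self.tmax)
        # The sowing window needs the preceding day's rain, hence 16 days.
        if self.pheno.sowing_idx < 16:
            raise ValueError("slice must start >= 16 days before sowing")
        if self.pheno.maturity_idx + 25 >= n:
            raise ValueError("slice must extend >= 25 days past maturity")


@dataclass(frozen=True)
class EventFlags:
    """Binary event outcomes for one crop season."""

    harvest_year: int
    frost_no_snow: bool
    late_frost: bool
    wet_early_season: bool
    lodging_risk: bool
    grainfill_heat: bool
    adverse_sowing: bool
    adverse_harvest: bool

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in EVENT_NAMES}


def detect_frost_no_snow(cy: CropYear) -> bool:
    """Severe frost on bare ground anywhere in the sowing-maturity span."""
    lo, hi = cy.pheno.sowing_idx, cy.pheno.maturity_idx + 1
    return bool(np.any(
        (cy.tmin[lo:hi] <= -20.0)
        & (cy.snow_depth_cm[lo:hi] < SNOW_COVER_LIMIT_CM)
    ))


def detect_late_frost(cy: CropYear) -> bool:
    """Frost after loss of winter hardiness (warm-spell state machine).

    Hardiness is lost after >= 5 consecutive days with mean temperature
    >= 10 degC and regained only after mean temperature stays below 10 degC
    for more than 2 consecutive days.  The state resets at each sowing.
    """
    lo, hi = cy.pheno.sowing_idx, cy.pheno.maturity_idx + 1
    tmean = cy.tmean[lo:hi]
    tmin = cy.tmin[lo:hi]
    hardy = True
    warm_run = 0
    cold_run = 0
    for d in range(len(tmean)):
        if tmean[d] >= 10.0:
            warm_run += 1
            cold_run = 0
            if warm_run >= 5:
                hardy = False
        else:
            cold_run += 1
            warm_run = 0
            if cold_run > 2:
                hardy = True
        if not hardy and tmin[d] <= -2.0:
            return True
    return False


def detect_wet_early_season(cy: CropYear) -> bool:
    """More than 60 warm waterlogged days between sowing and anthesis."""
    lo, hi = cy.pheno.sowing_idx, cy.pheno.anthesis_idx  # [sowing, anthesis)
    count = int(np.sum(cy.at_fc[lo:hi] & (cy.tmean[lo:hi] >= 3.0)))
    return count > 60


def detect_lodging_risk(cy: CropYear) -> bool:
    """At least 2 heavy-rain (or rain-on-saturated-soil) days late season."""
    lo = cy.pheno.anthesis_idx
    hi = cy.pheno.maturity_idx - 5 + 1  # anthesis .. maturity-5 inclusive
    if hi <= lo:
        return False
    rain = cy.precip[lo:hi]
    prev_at_fc = cy.at_fc[lo - 1:hi - 1]
    qualifying = (rain > 40.0) | ((rain > 20.0) & prev_at_fc)
    return int(np.sum(qualifying)) >= 2


def detect_grainfill_heat(cy: CropYear) -> bool:
    """tmax > 35 degC on >= 3 days from anthesis+5 to maturity."""
    lo = cy.pheno.anthesis_idx + 5
    hi = cy.pheno.maturity_idx + 1
    if hi <= lo:
        return False
    return int(np.sum(cy.tmax[lo:hi] > 35.0)) >= 3


def _workable_days(cy, lo, hi, sat_lo, sat_hi, rain_max, prev_rain_max):
    sat = cy.top_saturation[lo:hi]
    rain = cy.precip[lo:hi]
    prev_rain = cy.precip[lo - 1:hi - 1]
    ok = (sat < sat_hi) & (rain < rain_max) & (prev_rain <= prev_rain_max)
    if sat_lo is not None:
        ok &= sat > sat_lo
    return int(np.sum(ok))


def detect_adverse_sowing(cy: CropYear) -> bool:
    """Fewer than 3 workable days in the sowing window (sowing +/- 15 days)."""
    lo = cy.pheno.sowing_idx - 15
    hi = cy.pheno.sowing_idx + 15 + 1
    workable = _workable_days(cy, lo, hi, sat_lo=0.05, sat_hi=0.90,
                              rain_max=5.0, prev_rain_max=10.0)
    return workable < 3


def detect_adverse_harvest(cy: CropYear) -> bool:
    """Fewer than 3 workable days from maturity+5 to maturity+25."""
    lo = cy.pheno.maturity_idx + 5
    hi = cy.pheno.maturity_idx + 25 + 1
    workable = _workable_days(cy, lo, hi, sat_lo=None, sat_hi=0.85,
                              rain_max=0.5, prev_rain_max=5.0)
    return workable < 3


def detect_all(cy: CropYear) -> EventFlags:
    """Evaluate all seven detectors on one crop season."""
    return EventFlags(
        harvest_year=cy.harvest_year,
        frost_no_snow=detect_frost_no_snow(cy),
        late_frost=detect_late_frost(cy),
        wet_early_season=detect_wet_early_season(cy),
        lodging_risk=detect_lodging_risk(cy),
        grainfill_heat=detect_grainfill_heat(cy),
        adverse_sowing=detect_adverse_sowing(cy),
        adverse_harvest=detect_adverse_harvest(cy),
    )


def event_probability(flags: list[EventFlags]) -> dict:
    """Occurrence probability of each event over the retained years.

    Returns ``{event: probability}`` plus ``n_years``.  Spin-up years are
    excluded upstream; at least one retained year is required.
    """
    n = len(flags)
    if n == 0:
        raise ValueError("no retained years")
    out = {name: sum(getattr(f, name) for f in flags) / n for name in EVENT_NAMES}
    out["n_years"] = n
    return out
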
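"""Independent day-by-day re-implementations of the adverse-event triggers.

Deliberately written as plain Python scans (no vectorisation, no shared code
with the package) so they can serve as an oracle for the production
detectors.  Random crop years for the comparison are built here too.
"""

from __future__ import annotations

import numpy as np

import agriwx as ax
from agriwx.phenology import PhenoDates


def naive_frost_no_snow(cy):
    for d in range(cy.pheno.sowing_idx, cy.pheno.maturity_idx + 1):
        if cy.tmin[d] <= -20.0 and cy.snow_depth_cm[d] < 1.0:
            return True
    return False


def naive_late_frost(cy):
    hardy = True
    consec_warm = 0
    consec_cold = 0
    for d in range(cy.pheno.sowing_idx, cy.pheno.maturity_idx + 1):
        mean_t = (cy.tmax[d] + cy.tmin[d]) / 2.0
        if mean_t >= 10.0:
            consec_warm += 1
            consec_cold = 0
        else:
            consec_cold += 1
            consec_warm = 0
        if consec_warm >= 5:
            hardy = False
        if consec_cold > 2:
            hardy = True
        if (not hardy) and cy.tmin[d] <= -2.0:
            return True
    return False


def naive_wet_early_season(cy):
    n = 0
    for d in range(cy.pheno.sowing_idx, cy.pheno.anthesis_idx):
        mean_t = (cy.tmax[d] + cy.tmin[d]) / 2.0
        if cy.at_fc[d] and mean_t >= 3.0:
            n += 1
    return n > 60


def naive_lodging_risk(cy):
    n = 0
    for d in range(cy.pheno.anthesis_idx, cy.pheno.maturity_idx - 5 + 1):
        heavy = cy.precip[d] > 40.0
        moderate_on_wet = cy.precip[d] > 20.0 and bool(cy.at_fc[d - 1])
        if heavy or moderate_on_wet:
            n += 1
    return n >= 2


def naive_grainfill_heat(cy):
    n = 0
    for d in range(cy.pheno.anthesis_idx + 5, cy.pheno.maturity_idx + 1):
        if cy.tmax[d] > 35.0:
            n += 1
    return n >= 3


def naive_adverse_sowing(cy):
    workable = 0
    for d in range(cy.pheno.sowing_idx - 15, cy.pheno.sowing_idx + 15 + 1):
        if (0.05 < cy.top_saturation[d] < 0.90
                and cy.precip[d] < 5.0
                and cy.precip[d - 1] <= 10.0):
            workable += 1
    return workable < 3


def naive_adverse_harvest(cy):
    workable = 0
    for d in range(cy.pheno.maturity_idx + 5, cy.pheno.maturity_idx + 25 + 1):
        if (cy.top_saturation[d] < 0.85
                and cy.precip[d] < 0.5
                and cy.precip[d - 1] <= 5.0):
            workable += 1
    return workable < 3


NAIVE = {
    "frost_no_snow": naive_frost_no_snow,
    "late_frost": naive_late_frost,
    "wet_early_season": naive_wet_early_season,
    "lodging_risk": naive_lodging_risk,
    "grainfill_heat": naive_grainfill_heat,
    "adverse_sowing": naive_adverse_sowing,
    "adverse_harvest": naive_adverse_harvest,
}


def random_crop_year(rng) -> ax.CropYear:
    """A random crop season engineered to exercise every trigger threshold."""
    n = 460
    sow = int(rng.integers(16, 40))
    anth = sow + int(rng.integers(180, 260))
    mat = anth + int(rng.integers(30, 80))
    emerg = sow + int(rng.integers(5, 40))
    if emerg >= anth:
        emerg = anth - 1
    pheno = PhenoDates(
        sowing_idx=sow, emergence_idx=emerg, anthesis_idx=anth,
        maturity_idx=mat, sowing_doy=293,
        emergence_doy=(293 - 1 + (emerg - sow)) % 365 + 1,
        anthesis_doy=(293 - 1 + (anth - sow)) % 365 + 1,
        maturity_doy=(293 - 1 + (mat - sow)) % 365 + 1,
        temperature_rate_sowing_anthesis=1.0,
        temperature_rate_anthesis_maturity=1.0,
    )
    # Heavy-tailed weather so that rare triggers fire often enough to matter;
    # a fraction of years is drawn from a saturated/rainy regime so the
    # workability-based events (sowing/harvest windows) also fire.
    wet_regime = rng.random() < 0.25
    tmin = rng.normal(2.0, 9.0, n) + rng.choice([0.0, -18.0, 30.0], n,
                                                p=[0.90, 0.05, 0.05])
    tmax = tmin + rng.uniform(0.0, 12.0, n)
    p_rain = 0.85 if wet_regime else 0.45
    precip = np.where(rng.random(n) < p_rain,
                      rng.gamma(0.6, 9.0, n), 0.0)
    precip += np.where(rng.random(n) < 0.03, rng.uniform(30, 60, n), 0.0)
    at_fc = rng.random(n) < (0.7 if wet_regime else 0.35)
    if wet_regime:
        top_sat = rng.uniform(0.8, 1.1, n)
    else:
        top_sat = rng.uniform(0.0, 1.1, n)
    snow = np.where(rng.random(n) < 0.2, rng.uniform(0.0, 6.0, n), 0.0)
    return ax.CropYear(
        harvest_year=1, tmax=tmax, tmin=tmin, precip=precip,
        at_fc=at_fc, top_saturation=top_sat, snow_depth_cm=snow, pheno=pheno,
    )
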
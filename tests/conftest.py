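"""Shared fixtures: climatologies, generated forcing and full pipeline cells.

The expensive objects (multi-century cells) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import agriwx as ax
from agriwx import metforcing, soilwater


@pytest.fixture(scope="session")
def baseline_clim():
    return ax.synthetic_site_climatology()


@pytest.fixture(scope="session")
def wet_clim():
    """A wet western-style site, where waterlogging events actually occur."""
    return ax.synthetic_site_climatology(wetness=1.3)


def make_forcing(clim, n_years, seed):
    """Generate weather and derive rs/et0/tmean arrays for direct model use."""
    series = ax.generate_series(clim, n_years, seed)
    doy = series["doy"].to_numpy()
    tmax = series["tmax"].to_numpy()
    tmin = series["tmin"].to_numpy()
    precip = series["precip"].to_numpy()
    ra, n_dl = metforcing.extraterrestrial_radiation(clim.latitude, doy)
    rs = metforcing.sunshine_to_radiation(series["sun_hours"].to_numpy(), ra, n_dl)
    et0 = metforcing.penman_monteith_et0(tmax, tmin, rs, clim.latitude, doy)
    return {
        "series": series, "doy": doy, "tmax": tmax, "tmin": tmin,
        "precip": precip, "tmean": (tmax + tmin) / 2, "rs": rs, "et0": et0,
    }


@pytest.fixture(scope="session")
def forcing_60(baseline_clim):
    return make_forcing(baseline_clim, 60, seed=11)


@pytest.fixture(scope="session")
def forcing_300(baseline_clim):
    """Three centuries of baseline forcing for conservation/spin-up checks."""
    return make_forcing(baseline_clim, 300, seed=21)


@pytest.fixture(scope="session")
def traj_300(forcing_300):
    return soilwater.run_water_balance(
        forcing_300["tmean"], forcing_300["precip"], forcing_300["et0"],
        soilwater.SOIL_PROFILES["default180"])


@pytest.fixture(scope="session")
def baseline_cell_300(baseline_clim):
    """Full 300-year baseline cell with both stress soil profiles."""
    cfg = ax.ExperimentConfig(
        sites=[ax.SiteConfig(name="base", latitude=52.0)],
        n_years=300, spin_up_years=50,
        stress_profiles=("hafren177", "light127"),
    )
    return ax.run_cell(baseline_clim, None, cfg, np.random.SeedSequence(101))


@pytest.fixture(scope="session")
def small_cell_config():
    return ax.ExperimentConfig(
        sites=[ax.SiteConfig(name="s", latitude=52.0)],
        n_years=40, spin_up_years=5,
    )


@pytest.fixture(scope="session")
def small_cell(baseline_clim, small_cell_config):
    return ax.run_cell(baseline_clim, None, small_cell_config,
                       np.random.SeedSequence(7))
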
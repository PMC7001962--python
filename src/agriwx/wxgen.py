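"""Stochastic daily weather generation for a single site.

The generator is a Richardson-type parametric model fitted per calendar month:

* precipitation occurrence follows a two-state first-order Markov chain
  (wet-after-wet and wet-after-dry probabilities);
* wet-day amounts are gamma distributed (shape, scale fitted by moments);
* daily maximum and minimum temperature are normals conditioned on the wet/dry
  state, with a bivariate AR(1) residual giving day-to-day persistence and
  tmax-tmin cross-correlation;
* the daily sunshine fraction (bright sunshine / astronomical daylength) is a
  clipped normal conditioned on the wet/dry state, which makes radiation
  anticorrelated with rain days.

Climate-change "change factors" perturb the fitted monthly parameters:
additive shifts of the temperature means and a multiplicative factor on the
gamma scale, so that the expected monthly precipitation scales exactly by the
stated ratio while occurrence statistics are untouched.

A 365-day calendar is used everywhere (29 February is dropped on ingest), so
every simulated year is structurally identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metforcing

__all__ = [
    "WET_DAY_THRESHOLD_MM",
    "DAYS_IN_MONTH",
    "MONTH_OF_DOY",
    "SiteClimatology",
    "ChangeFactorSet",
    "QCReport",
    "SiteRejectedError",
    "qc_series",
    "fit_climatology",
    "apply_change_factors",
    "generate_series",
    "make_synthetic_ensemble",
    "synthetic_site_climatology",
    "read_weather_csv",
    "write_weather_csv",
    "read_change_factor_csv",
    "write_change_factor_csv",
    "CO2_PPM",
]

#: Precipitation at or above this depth classifies a day as wet when fitting.
WET_DAY_THRESHOLD_MM = 0.1

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: Zero-based month index for each day of a 365-day year (doy 1 -> index 0).
MONTH_OF_DOY = np.repeat(np.arange(12), DAYS_IN_MONTH)

_MONTH_START_DOY = np.concatenate([[0], np.cumsum(DAYS_IN_MONTH)])[:12] + 1

#: Scenario CO2 concentrations (ppm), carried as metadata only.
CO2_PPM = {
    ("baseline", "1981-2010"): 364.0,
    ("RCP4.5", "2050"): 487.0,
    ("RCP8.5", "2050"): 541.0,
    ("RCP4.5", "2090"): 533.0,
    ("RCP8.5", "2090"): 844.0,
}


class SiteRejectedError(ValueError):
    """Raised when an observed record fails the site-selection rule."""


def _arr12(x):
    a = np.asarray(x, dtype=float)
    if a.shape != (12,):
        raise ValueError(f"expected 12 monthly values, got shape {a.shape}")
    return a


@dataclass
class SiteClimatology:
    """Monthly statistical parameters driving daily weather generation.

    All per-month arrays have 12 entries (January first).  Temperature and
    sunshine statistics are conditioned on the wet/dry state of the day.
    ``temp_autocorr`` is the lag-1 autocorrelation of the standardised
    temperature residuals and ``temp_cross_corr`` the correlation between the
    tmax and tmin innovations.
    """

    latitude: float
    p_wet_wet: np.ndarray
    p_wet_dry: np.ndarray
    precip_shape: np.ndarray
    precip_scale: np.ndarray
    tmax_mean_wet: np.ndarray
    tmax_sd_wet: np.ndarray
    tmax_mean_dry: np.ndarray
    tmax_sd_dry: np.ndarray
    tmin_mean_wet: np.ndarray
    tmin_sd_wet: np.ndarray
    tmin_mean_dry: np.ndarray
    tmin_sd_dry: np.ndarray
    sun_frac_mean_wet: np.ndarray
    sun_frac_sd_wet: np.ndarray
    sun_frac_mean_dry: np.ndarray
    sun_frac_sd_dry: np.ndarray
    temp_autocorr: float = 0.6
    temp_cross_corr: float = 0.7

    def __post_init__(self):
        for name in (
            "p_wet_wet", "p_wet_dry", "precip_shape", "precip_scale",
            "tmax_mean_wet", "tmax_sd_wet", "tmax_mean_dry", "tmax_sd_dry",
            "tmin_mean_wet", "tmin_sd_wet", "tmin_mean_dry", "tmin_sd_dry",
            "sun_frac_mean_wet", "sun_frac_sd_wet",
            "sun_frac_mean_dry", "sun_frac_sd_dry",
        ):
            setattr(self, name, _arr12(getattr(self, name)))
        self.validate()

    def validate(self):
        if not (np.all(self.p_wet_wet >= 0) and np.all(self.p_wet_wet <= 1)):
            raise ValueError("p_wet_wet outside [0, 1]")
        if not (np.all(self.p_wet_dry >= 0) and np.all(self.p_wet_dry <= 1)):
            raise ValueError("p_wet_dry outside [0, 1]")
        if np.any(self.precip_shape <= 0) or np.any(self.precip_scale <= 0):
            raise ValueError("gamma shape and scale must be positive")
        for name in (
            "tmax_sd_wet", "tmax_sd_dry", "tmin_sd_wet", "tmin_sd_dry",
            "sun_frac_sd_wet", "sun_frac_sd_dry",
        ):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 < self.temp_autocorr < 1.0:
            raise ValueError("temp_autocorr must be in (-1, 1)")
        if not -1.0 < self.temp_cross_corr < 1.0:
            raise ValueError("temp_cross_corr must be in (-1, 1)")

    # -- derived expectations -------------------------------------------------

    def stationary_wet_prob(self) -> np.ndarray:
        """Stationary wet-day probability of the monthly two-state chain."""
        p01, p11 = self.p_wet_dry, self.p_wet_wet
        denom = 1.0 + p01 - p11
        return np.where(denom > 0, p01 / np.where(denom > 0, denom, 1.0), 1.0)

    def expected_monthly_precip(self) -> np.ndarray:
        """Expected total precipitation per month (mm), at chain stationarity."""
        return (
            DAYS_IN_MONTH
            * self.stationary_wet_prob()
            * self.precip_shape
            * self.precip_scale
        )

    def expected_monthly_tmax(self) -> np.ndarray:
        pi = self.stationary_wet_prob()
        return pi * self.tmax_mean_wet + (1 - pi) * self.tmax_mean_dry

    def expected_monthly_tmin(self) -> np.ndarray:
        pi = self.stationary_wet_prob()
        return pi * self.tmin_mean_wet + (1 - pi) * self.tmin_mean_dry

    def monthly_tmax_variance(self) -> np.ndarray:
        """Total daily tmax variance per month (wet/dry mixture)."""
        pi = self.stationary_wet_prob()
        mean = self.expected_monthly_tmax()
        return (
            pi * (self.tmax_sd_wet**2 + (self.tmax_mean_wet - mean) ** 2)
            + (1 - pi) * (self.tmax_sd_dry**2 + (self.tmax_mean_dry - mean) ** 2)
        )

    def monthly_tmin_variance(self) -> np.ndarray:
        pi = self.stationary_wet_prob()
        mean = self.expected_monthly_tmin()
        return (
            pi * (self.tmin_sd_wet**2 + (self.tmin_mean_wet - mean) ** 2)
            + (1 - pi) * (self.tmin_sd_dry**2 + (self.tmin_mean_dry - mean) ** 2)
        )

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        out = {"latitude": self.latitude,
               "temp_autocorr": self.temp_autocorr,
               "temp_cross_corr": self.temp_cross_corr}
        for name in _CLIM_ARRAY_FIELDS:
            out[name] = [float(v) for v in getattr(self, name)]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SiteClimatology":
        kwargs = {k: d[k] for k in ("latitude", "temp_autocorr", "temp_cross_corr")}
        for name in _CLIM_ARRAY_FIELDS:
            kwargs[name] = np.asarray(d[name], dtype=float)
        return cls(**kwargs)


_CLIM_ARRAY_FIELDS = [
    "p_wet_wet", "p_wet_dry", "precip_shape", "precip_scale",
    "tmax_mean_wet", "tmax_sd_wet", "tmax_mean_dry", "tmax_sd_dry",
    "tmin_mean_wet", "tmin_sd_wet", "tmin_mean_dry", "tmin_sd_dry",
    "sun_frac_mean_wet", "sun_frac_sd_wet", "sun_frac_mean_dry", "sun_frac_sd_dry",
]


@dataclass(frozen=True)
class ChangeFactorSet:
    """One climate model x scenario x period perturbation of a climatology."""

    gcm_id: str
    scenario: str
    period: str
    dtmax: np.ndarray        # additive degC, 12 months
    dtmin: np.ndarray        # additive degC
    precip_ratio: np.ndarray  # multiplicative, >= 0
    co2_ppm: float = 364.0

    def __post_init__(self):
        object.__setattr__(self, "dtmax", _arr12(self.dtmax))
        object.__setattr__(self, "dtmin", _arr12(self.dtmin))
        object.__setattr__(self, "precip_ratio", _arr12(self.precip_ratio))
        if np.any(self.precip_ratio < 0):
            raise ValueError("precip_ratio must be >= 0")

    @classmethod
    def neutral(cls, gcm_id="neutral", scenario="baseline", period="1981-2010",
                co2_ppm=364.0) -> "ChangeFactorSet":
        z = np.zeros(12)
        return cls(gcm_id, scenario, period, z, z.copy(), np.ones(12), co2_ppm)

    def annual_mean_warming(self) -> float:
        """Annual mean of the monthly mean-temperature shift, degC."""
        monthly = (self.dtmax + self.dtmin) / 2.0
        return float(np.average(monthly, weights=DAYS_IN_MONTH))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Summary of a quality-control pass over an observed daily record."""

    n_days: int
    n_flagged: int
    flags_by_rule: dict = field(default_factory=dict)
    missing_fraction: dict = field(default_factory=dict)

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_days if self.n_days else 0.0


#: Plausibility bounds for a temperate maritime record.
QC_BOUNDS = {
    "tmax": (-40.0, 50.0),
    "tmin": (-50.0, 45.0),
    "precip": (0.0, 400.0),
}


def qc_series(
    df: pd.DataFrame,
    latitude: float | None = None,
    max_missing_fraction: float = 0.10,
) -> tuple[pd.DataFrame, QCReport]:
    """Flag physically impossible values, gap-fill, and apply the site rule.

    Rules: tmax < tmin, precipitation outside [0, 400] mm, temperatures
    outside plausible magnitude bounds, and (when latitude is given) sunshine
    hours outside [0, daylength].  Flagged values are set missing and then
    filled by calendar-day climatological means (falling back to monthly
    means).  Sites where tmax, tmin or precip are missing on more than
    ``max_missing_fraction`` of days are rejected outright.
    """
    df = df.copy()
    n = len(df)
    if n == 0:
        raise ValueError("empty weather series")
    flags_by_rule: dict[str, int] = {}

    def _flag(mask, cols, rule):
        count = int(np.sum(mask))
        if count:
            flags_by_rule[rule] = flags_by_rule.get(rule, 0) + count
            for c in cols:
                df.loc[mask, c] = np.nan

    both = df["tmax"].notna() & df["tmin"].notna()
    _flag(both & (df["tmax"] < df["tmin"]), ["tmax", "tmin"], "tmax_lt_tmin")
    _flag(df["precip"].notna() & (df["precip"] < QC_BOUNDS["precip"][0]),
          ["precip"], "negative_precip")
    _flag(df["precip"].notna() & (df["precip"] > QC_BOUNDS["precip"][1]),
          ["precip"], "extreme_precip")
    for var in ("tmax", "tmin"):
        lo, hi = QC_BOUNDS[var]
        _flag(df[var].notna() & ((df[var] < lo) | (df[var] > hi)),
              [var], f"{var}_out_of_range")
    if "sun_hours" in df.columns and latitude is not None:
        dl = metforcing.daylength(latitude, df["doy"].to_numpy())
        sun = df["sun_hours"]
        _flag(sun.notna() & ((sun < 0) | (sun.to_numpy() > dl + 0.5)),
              ["sun_hours"], "sun_hours_out_of_range")

    # Site-selection rule on the essential variables, assessed after flagging.
    missing_fraction = {}
    for var in ("tmax", "tmin", "precip"):
        frac = float(df[var].isna().mean())
        missing_fraction[var] = frac
        if frac > max_missing_fraction:
            raise SiteRejectedError(
                f"site rejected: {var} missing on {frac:.1%} of days "
                f"(limit {max_missing_fraction:.0%})"
            )

    # Gap-fill by calendar-day climatology, then monthly climatology.
    fill_cols = [c for c in ("tmax", "tmin", "precip", "sun_hours")
                 if c in df.columns]
    for c in fill_cols:
        by_doy = df.groupby("doy")[c].transform("mean")
        df[c] = df[c].fillna(by_doy)
        by_month = df.groupby("month")[c].transform("mean")
        df[c] = df[c].fillna(by_month)
    if df[fill_cols].isna().any().any():
        raise ValueError("gap-filling failed: a variable is missing everywhere")
    # Filling can itself produce tmax < tmin on rare days; repair conservatively.
    swap = df["tmax"] < df["tmin"]
    if swap.any():
        mid = (df.loc[swap, "tmax"] + df.loc[swap, "tmin"]) / 2.0
        df.loc[swap, "tmax"] = mid
        df.loc[swap, "tmin"] = mid

    n_flagged = int(sum(flags_by_rule.values()))
    report = QCReport(n_days=n, n_flagged=n_flagged,
                      flags_by_rule=flags_by_rule,
                      missing_fraction=missing_fraction)
    return df, report


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_climatology(
    df: pd.DataFrame,
    latitude: float,
    wet_threshold: float = WET_DAY_THRESHOLD_MM,
    temp_autocorr: float = 0.6,
    temp_cross_corr: float = 0.7,
    min_years: int = 10,
) -> SiteClimatology:
    """Estimate monthly generator parameters from a daily record.

    The record must span at least ``min_years`` whole years.  Moment
    estimators are used throughout: transition probabilities are empirical
    frequencies, gamma parameters come from the wet-day mean and variance
    (shape = mean^2/var, scale = var/mean), and conditional temperature and
    sunshine-fraction statistics are sample means/sds on wet and dry days.
    Months with fewer than two wet days borrow precipitation parameters from
    the nearest month with data (a warning is logged).
    """
    if len(df) < min_years * 365:
        raise ValueError(
            f"need at least {min_years} whole years ({min_years * 365} days); "
            f"got {len(df)} days"
        )
    month = df["month"].to_numpy() - 1
    precip = df["precip"].to_numpy(dtype=float)
    tmax = df["tmax"].to_numpy(dtype=float)
    tmin = df["tmin"].to_numpy(dtype=float)
    wet = precip >= wet_threshold

    if "sun_hours" in df.columns and df["sun_hours"].notna().all():
        dl = metforcing.daylength(latitude, df["doy"].to_numpy())
        sun_frac = np.clip(np.divide(df["sun_hours"].to_numpy(dtype=float),
                                     np.maximum(dl, 1e-9)), 0.0, 1.0)
    elif "radiation" in df.columns and df["radiation"].notna().all():
        # Invert the Angstrom relation with the default coefficients.
        ra, _ = metforcing.extraterrestrial_radiation(latitude, df["doy"].to_numpy())
        frac = (df["radiation"].to_numpy(dtype=float) / np.maximum(ra, 1e-9) - 0.25) / 0.50
        sun_frac = np.clip(frac, 0.0, 1.0)
    else:
        raise ValueError("series must provide sun_hours or radiation on every day")

    shape = np.empty(12)
    scale = np.empty(12)
    p11 = np.empty(12)
    p01 = np.empty(12)
    stats = {k: np.empty(12) for k in _CLIM_ARRAY_FIELDS[4:]}

    wet_prev = np.concatenate([[False], wet[:-1]])
    first_day = np.zeros(len(df), dtype=bool)
    first_day[0] = True

    empty_months = []
    for m in range(12):
        sel = month == m
        w = wet[sel]
        # Transition counts exclude the very first record (no predecessor).
        selt = sel & ~first_day
        prev_w = wet_prev[selt]
        cur_w = wet[selt]
        n_from_wet = int(np.sum(prev_w))
        n_from_dry = int(np.sum(~prev_w))
        p11[m] = np.sum(cur_w & prev_w) / n_from_wet if n_from_wet else 0.0
        p01[m] = np.sum(cur_w & ~prev_w) / n_from_dry if n_from_dry else 0.0

        amounts = precip[sel][w]
        if amounts.size >= 2 and np.var(amounts) > 0:
            mean = amounts.mean()
            var = amounts.var(ddof=1)
            shape[m] = mean * mean / var
            scale[m] = var / mean
        else:
            shape[m] = np.nan
            scale[m] = np.nan
            empty_months.append(m)

        for var_name, values in (("tmax", tmax[sel]), ("tmin", tmin[sel]),
                                 ("sun_frac", sun_frac[sel])):
            for state, mask in (("wet", w), ("dry", ~w)):
                vals = values[mask]
                if vals.size == 0:  # degenerate: fall back to all-days stats
                    vals = values
                stats[f"{var_name}_mean_{state}"][m] = vals.mean()
                stats[f"{var_name}_sd_{state}"][m] = (
                    vals.std(ddof=1) if vals.size > 1 else 0.0
                )

    if empty_months:
        warnings.warn(
            f"months with <2 wet days: {[m + 1 for m in empty_months]}; "
            "borrowing precipitation parameters from the nearest month",
            stacklevel=2,
        )
        for m in empty_months:
            for off in (1, -1, 2, -2, 3, -3, 4, -4, 5, -5, 6):
                mm = (m + off) % 12
                if not np.isnan(shape[mm]):
                    shape[m] = shape[mm]
                    scale[m] = scale[mm]
                    break
            else:
                # Effectively rain-free site: minimal drizzle parameters.
                shape[m], scale[m] = 1.0, 1.0

    return SiteClimatology(
        latitude=latitude,
        p_wet_wet=p11,
        p_wet_dry=p01,
        precip_shape=shape,
        precip_scale=scale,
        temp_autocorr=temp_autocorr,
        temp_cross_corr=temp_cross_corr,
        **stats,
    )


# ---------------------------------------------------------------------------
# Change factors
# ---------------------------------------------------------------------------

def apply_change_factors(base: SiteClimatology, cf: ChangeFactorSet) -> SiteClimatology:
    """Perturb a climatology by monthly change factors.

    Temperature means (wet and dry conditionals alike) shift additively;
    the wet-day gamma scale is multiplied by the precipitation ratio, so the
    expected monthly precipitation scales exactly by that ratio.  Occurrence
    probabilities, variances and sunshine statistics are unchanged.
    """
    if np.any(cf.precip_ratio < 0):
        raise ValueError("precip_ratio must be >= 0")
    ratio = np.maximum(cf.precip_ratio, 1e-9)  # keep scale strictly positive
    return replace(
        base,
        tmax_mean_wet=base.tmax_mean_wet + cf.dtmax,
        tmax_mean_dry=base.tmax_mean_dry + cf.dtmax,
        tmin_mean_wet=base.tmin_mean_wet + cf.dtmin,
        tmin_mean_dry=base.tmin_mean_dry + cf.dtmin,
        precip_scale=base.precip_scale * ratio,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_series(
    clim: SiteClimatology,
    n_years: int,
    seed,
    start_year: int = 1,
) -> pd.DataFrame:
    """Generate ``n_years`` of synthetic daily weather (365-day years).

    Years are generated in parallel: each year's occurrence chain and
    temperature residuals start from their stationary January distribution,
    and the day loop runs over the 365 calendar days.  The result is a
    DataFrame with columns ``year, month, day, doy, tmax, tmin, precip,
    sun_hours`` and attrs recording latitude and the seed.  Identical inputs
    give bit-identical output.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    clim.validate()
    rng = np.random.default_rng(seed)
    ny = int(n_years)
    mo = MONTH_OF_DOY  # (365,), zero-based

    # Occurrence chain.
    wet = np.empty((ny, 365), dtype=bool)
    u = rng.random((ny, 365))
    pi0 = clim.stationary_wet_prob()[0]
    wet[:, 0] = u[:, 0] < pi0
    for d in range(1, 365):
        m = mo[d]
        p = np.where(wet[:, d - 1], clim.p_wet_wet[m], clim.p_wet_dry[m])
        wet[:, d] = u[:, d] < p

    # Wet-day amounts.
    shape = np.broadcast_to(clim.precip_shape[mo], (ny, 365))
    scale = np.broadcast_to(clim.precip_scale[mo], (ny, 365))
    amounts = rng.gamma(shape, scale)
    precip = np.where(wet, amounts, 0.0)

    # Bivariate AR(1) standardised temperature residuals.
    rho = clim.temp_autocorr
    r = clim.temp_cross_corr
    e1 = rng.standard_normal((ny, 365))
    e2raw = rng.standard_normal((ny, 365))
    e2 = r * e1 + np.sqrt(1.0 - r * r) * e2raw
    z1 = np.empty((ny, 365))
    z2 = np.empty((ny, 365))
    z1[:, 0] = e1[:, 0]
    z2[:, 0] = e2[:, 0]
    innov = np.sqrt(1.0 - rho * rho)
    for d in range(1, 365):
        z1[:, d] = rho * z1[:, d - 1] + innov * e1[:, d]
        z2[:, d] = rho * z2[:, d - 1] + innov * e2[:, d]

    def _cond(wet_arr, dry_arr):
        return np.where(wet, wet_arr[mo][None, :], dry_arr[mo][None, :])

    tmax = _cond(clim.tmax_mean_wet, clim.tmax_mean_dry) + \
        _cond(clim.tmax_sd_wet, clim.tmax_sd_dry) * z1
    tmin = _cond(clim.tmin_mean_wet, clim.tmin_mean_dry) + \
        _cond(clim.tmin_sd_wet, clim.tmin_sd_dry) * z2
    tmin = np.minimum(tmin, tmax)  # constructive invariant, rare with sane params

    # Sunshine fraction, anticorrelated with rain through the conditioning.
    sf = _cond(clim.sun_frac_mean_wet, clim.sun_frac_mean_dry) + \
        _cond(clim.sun_frac_sd_wet, clim.sun_frac_sd_dry) * rng.standard_normal((ny, 365))
    sf = np.clip(sf, 0.0, 1.0)
    doy = np.arange(1, 366)
    dl = metforcing.daylength(clim.latitude, doy)
    sun_hours = sf * dl[None, :]

    years = np.repeat(np.arange(start_year, start_year + ny), 365)
    df = pd.DataFrame(
        {
            "year": years,
            "month": np.tile(mo + 1, ny),
            "day": np.tile(doy - _MONTH_START_DOY[mo] + 1, ny),
            "doy": np.tile(doy, ny),
            "tmax": tmax.ravel(),
            "tmin": tmin.ravel(),
            "precip": precip.ravel(),
            "sun_hours": sun_hours.ravel(),
        }
    )
    df.attrs["latitude"] = clim.latitude
    df.attrs["seed"] = seed
    return df


# ---------------------------------------------------------------------------
# Synthetic fixtures: a UK-like site and a pseudo-GCM change-factor ensemble
# ---------------------------------------------------------------------------

def _seasonal(jan_value, jul_value):
    """Cosine interpolation between a January and a July value, 12 months."""
    m = np.arange(12)
    s = np.cos(2.0 * np.pi * m / 12.0)  # +1 in Jan, -1 in Jul
    mid = (jan_value + jul_value) / 2.0
    amp = (jan_value - jul_value) / 2.0
    return mid + amp * s


def synthetic_site_climatology(
    latitude: float = 52.0,
    wetness: float = 1.0,
    warmth: float = 0.0,
    temp_autocorr: float = 0.6,
    temp_cross_corr: float = 0.7,
) -> SiteClimatology:
    """A parametric temperate-maritime (UK-like) site climatology.

    Emulates a lowland England station: ~650 mm annual rainfall with weak
    seasonality, persistent rain spells (wet-after-wet ~0.65 in winter),
    skewed wet-day amounts, cool cloudy winters and mild summers.  ``wetness``
    scales the wet-day gamma scale (a drier east-coast site ~0.8, a wet
    western site ~1.4) and ``warmth`` shifts all temperature means (degC), so
    multiple distinct sites can be declared from one function.  Deterministic.
    """
    tmax_dry = _seasonal(7.5, 22.0) + warmth
    tmin_dry = _seasonal(1.0, 11.5) + warmth
    return SiteClimatology(
        latitude=latitude,
        p_wet_wet=_seasonal(0.65, 0.55),
        p_wet_dry=_seasonal(0.30, 0.22),
        precip_shape=np.full(12, 0.75),
        precip_scale=_seasonal(5.3, 6.7) * wetness,
        tmax_mean_wet=tmax_dry - 1.5,
        tmax_sd_wet=_seasonal(2.5, 3.0),
        tmax_mean_dry=tmax_dry,
        tmax_sd_dry=_seasonal(2.8, 3.4),
        tmin_mean_wet=tmin_dry + 1.0,
        tmin_sd_wet=_seasonal(2.8, 2.2),
        tmin_mean_dry=tmin_dry,
        tmin_sd_dry=_seasonal(3.2, 2.5),
        sun_frac_mean_wet=_seasonal(0.10, 0.25),
        sun_frac_sd_wet=np.full(12, 0.10),
        sun_frac_mean_dry=_seasonal(0.25, 0.45),
        sun_frac_sd_dry=np.full(12, 0.15),
        temp_autocorr=temp_autocorr,
        temp_cross_corr=temp_cross_corr,
    )


def make_synthetic_ensemble(
    seed,
    n_members: int = 16,
    scenario: str = "RCP8.5",
    period: str = "2050",
) -> list[ChangeFactorSet]:
    """A pseudo-GCM ensemble of change-factor sets.

    Members span the envelope reported for mid-century UK projections: winter
    precipitation change from -10% to +40%, summer change +/-30%, and annual
    mean warming between 0.2 and 3.0 degC with amplified summer warming.  The
    first member is a designated "wet" member (the top of the winter envelope)
    and the second a designated "dry" member (drier winter and summer); the
    rest are sampled uniformly inside the envelope.  With ``n_members=1`` a
    single neutral member is returned.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    co2 = CO2_PPM.get((scenario, period), 541.0)
    if n_members == 1:
        return [ChangeFactorSet.neutral("neutral", scenario, period, co2)]

    rng = np.random.default_rng(seed)
    m = np.arange(12)
    s = np.cos(2.0 * np.pi * m / 12.0)  # +1 Jan, -1 Jul

    def member(idx, label, winter_ratio, summer_ratio, warming):
        mid = (winter_ratio + summer_ratio) / 2.0
        amp = (winter_ratio - summer_ratio) / 2.0
        ratio = mid + amp * s
        dt = warming * (1.0 - 0.3 * s)  # amplified summer warming, annual mean = warming
        return ChangeFactorSet(
            gcm_id=label, scenario=scenario, period=period,
            dtmax=dt * 1.1, dtmin=dt * 0.9,
            precip_ratio=ratio, co2_ppm=co2,
        )

    members = [
        member(0, "SYN-GCM-01-wet", 1.40, 1.05, 1.8),
        member(1, "SYN-GCM-02-dry", 0.90, 0.70, 2.2),
    ]
    for i in range(2, n_members):
        winter = rng.uniform(0.90, 1.40)
        summer = rng.uniform(0.70, 1.30)
        warming = rng.uniform(0.2, 3.0)
        members.append(member(i, f"SYN-GCM-{i + 1:02d}", winter, summer, warming))
    return members[:n_members]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_weather_csv(path) -> pd.DataFrame:
    """Read a daily weather CSV with ISO-8601 dates into the internal layout.

    Expected columns: ``date,tmax,tmin,precip,sun_hours[,radiation]``.
    29 February rows are dropped (365-day calendar); ``year, month, day, doy``
    columns are derived from the date string.  Raises with a line number on an
    unparseable record.
    """
    df = pd.read_csv(path, dtype={"date": str})
    required = {"date", "tmax", "tmin", "precip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    years = np.empty(len(df), dtype=int)
    months = np.empty(len(df), dtype=int)
    days = np.empty(len(df), dtype=int)
    for i, s in enumerate(df["date"]):
        try:
            y, mth, d = str(s).split("-")
            years[i], months[i], days[i] = int(y), int(mth), int(d)
            if not (1 <= months[i] <= 12 and 1 <= days[i] <= 31):
                raise ValueError
        except Exception:
            raise ValueError(
                f"unparseable date {s!r} at line {i + 2} of {path}"
            ) from None
    df["year"], df["month"], df["day"] = years, months, days
    df = df[~((df["month"] == 2) & (df["day"] == 29))].reset_index(drop=True)
    df["doy"] = _MONTH_START_DOY[df["month"].to_numpy() - 1] + df["day"].to_numpy() - 1
    return df


def write_weather_csv(df: pd.DataFrame, path) -> None:
    """Write a daily series in the input CSV dialect (ISO dates, 365-day years)."""
    out = pd.DataFrame({
        "date": [f"{y:04d}-{m:02d}-{d:02d}"
                 for y, m, d in zip(df["year"], df["month"], df["day"])],
    })
    for c in ("tmax", "tmin", "precip", "sun_hours", "radiation"):
        if c in df.columns:
            out[c] = np.round(df[c].to_numpy(dtype=float), 4)
    out.to_csv(path, index=False)


def write_change_factor_csv(members: list[ChangeFactorSet], path) -> None:
    """Write change-factor sets in long form (one row per member-month)."""
    rows = []
    for cf in members:
        for m in range(12):
            rows.append({
                "gcm": cf.gcm_id, "scenario": cf.scenario, "period": cf.period,
                "month": m + 1, "dtmax": cf.dtmax[m], "dtmin": cf.dtmin[m],
                "precip_ratio": cf.precip_ratio[m], "co2_ppm": cf.co2_ppm,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_change_factor_csv(path) -> list[ChangeFactorSet]:
    """Read change-factor sets written by :func:`write_change_factor_csv`."""
    df = pd.read_csv(path)
    members = []
    for (gcm, scen, period), grp in df.groupby(["gcm", "scenario", "period"],
                                               sort=False):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"change-factor set {gcm}/{scen}/{period} lacks 12 months")
        members.append(ChangeFactorSet(
            gcm_id=str(gcm), scenario=str(scen), period=str(period),
            dtmax=grp["dtmax"].to_numpy(), dtmin=grp["dtmin"].to_numpy(),
            precip_ratio=grp["precip_ratio"].to_numpy(),
            co2_ppm=float(grp["co2_ppm"].iloc[0]),
        ))
    return members
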
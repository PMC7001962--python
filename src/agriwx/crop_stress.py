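"""Reduced process-based wheat model and the heat/drought/water stress indices.

The model is a radiation-use-efficiency (RUE) canopy: leaf area expands with
thermal time to a maximum, senesces during grain fill, and intercepts
photosynthetically active radiation (PAR = 0.5 Rs) with a Beer's-law canopy;
biomass accrues as RUE x intercepted PAR, and yield is biomass x harvest
index.  Water limitation enters through a daily stress factor, the ratio of
actual to reference evapotranspiration supplied by the soil water balance: in
rainfed mode it slows leaf expansion, accelerates senescence and scales the
day's assimilation.  Two cultivar sensitivities act multiplicatively on grain
number:

* drought sensitivity -- days in the window 10 days before to 5 days after
  flowering whose transpiration ratio falls below 0.9 reduce grain number by
  the factor min(1, ratio/0.9) per day;
* heat sensitivity -- days above 30 degC in the meiosis/fertilisation window
  (anthesis-10 .. anthesis) or early grain fill (anthesis+5 .. anthesis+12)
  sterilise a fraction s x (tmax - 30) of the grains (s = 0.05 per degC by
  default).

Four runs per season give the yield set: potential Y (irrigated, tolerant),
water-limited Yw (rainfed, tolerant), Ywd (rainfed, drought sensitive) and
Ywh (rainfed, heat sensitive).  The stress indices are the fractional yield
losses HSI = 1 - Ywh/Yw, DSI = 1 - Ywd/Yw, WSI = 1 - Yw/Y, each in [0, 1],
summarised by their mean and 95th percentile (the one-in-twenty-year loss)
over the retained years.  Elevated CO2 has no effect on water-use efficiency
here; scenario CO2 is metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phenology import PhenoDates, daily_thermal_time

__all__ = [
    "CropRunConfig",
    "YieldSet",
    "StressIndices",
    "water_stress_factor",
    "drought_grain_factor",
    "heat_sterility_factor",
    "simulate_crop",
    "run_yield_set",
    "compute_stress_indices",
]


@dataclass(frozen=True)
class CropRunConfig:
    """Parameters of one crop run (variant x water mode).

    Defaults are calibrated to give ~8 t/ha potential yield for a 20 October
    sowing under the package's temperate-maritime baseline.  ``rue`` is grams
    of dry matter per MJ of intercepted PAR.
    """

    variant: str = "tolerant"            # tolerant | heat_sensitive | drought_sensitive
    water_mode: str = "rainfed"          # potential | rainfed
    rue: float = 1.5                     # g DM / MJ PAR
    max_lai: float = 6.5
    lai_expansion_tt: float = 1100.0     # degC day from emergence to full canopy
    extinction_k: float = 0.6
    harvest_index_base: float = 0.5
    heat_sterility_slope: float = 0.05   # grain fraction lost per degC above 30
    co2_ppm: float = 364.0               # metadata only, no physiological effect

    def __post_init__(self):
        if self.rue <= 0:
            raise ValueError("rue must be positive")
        if not 0 < self.harvest_index_base < 1:
            raise ValueError("harvest_index_base must be in (0, 1)")
        if self.variant not in ("tolerant", "heat_sensitive", "drought_sensitive"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.water_mode not in ("potential", "rainfed"):
            raise ValueError(f"unknown water_mode {self.water_mode!r}")


@dataclass(frozen=True)
class YieldSet:
    """The four yields (t/ha) for one season."""

    y_potential: float
    y_water_limited: float
    y_drought_sensitive: float
    y_heat_sensitive: float

    def __post_init__(self):
        eps = 1e-9
        if not (0 - eps <= self.y_heat_sensitive <= self.y_water_limited + eps
                <= self.y_potential + 2 * eps):
            raise ValueError("yield ordering violated: need Ywh <= Yw <= Y")
        if not self.y_drought_sensitive <= self.y_water_limited + eps:
            raise ValueError("yield ordering violated: need Ywd <= Yw")


@dataclass
class StressIndices:
    """Per-year stress indices with their mean and 95th-percentile summaries."""

    hsi: np.ndarray
    dsi: np.ndarray
    wsi: np.ndarray
    hsi_mean: float
    dsi_mean: float
    wsi_mean: float
    hsi95: float
    dsi95: float
    wsi95: float


def water_stress_factor(eta, et0):
    """Daily water stress factor ETa/ET0, clipped to [0, 1] (1 when ET0 = 0)."""
    eta = np.asarray(eta, dtype=float)
    et0 = np.asarray(et0, dtype=float)
    ratio = np.divide(eta, et0, out=np.ones_like(eta), where=et0 > 0)
    out = np.clip(ratio, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def drought_grain_factor(transpiration_ratio: np.ndarray, pheno: PhenoDates) -> float:
    """Grain-number multiplier from drought around flowering.

    Product over the window [anthesis-10, anthesis+5] of min(1, ratio/0.9);
    equal to 1 when no window day's transpiration ratio falls below 0.9.
    """
    lo = pheno.anthesis_idx - 10
    hi = pheno.anthesis_idx + 5 + 1
    ratio = np.asarray(transpiration_ratio, dtype=float)[max(lo, 0):hi]
    return float(np.prod(np.minimum(1.0, ratio / 0.9)))


def heat_sterility_factor(
    tmax: np.ndarray,
    pheno: PhenoDates,
    slope: float = 0.05,
    threshold: float = 30.0,
) -> float:
    """Grain-number multiplier from heat around anthesis.

    For each day above the threshold in the windows [anthesis-10, anthesis]
    and [anthesis+5, anthesis+12], a fraction slope x (tmax - threshold)
    (clipped to [0, 1]) of grains is sterilised; the surviving fractions
    combine multiplicatively.
    """
    tmax = np.asarray(tmax, dtype=float)
    a = pheno.anthesis_idx
    days = np.concatenate([
        np.arange(max(a - 10, 0), a + 1),
        np.arange(a + 5, a + 12 + 1),
    ])
    days = days[days < len(tmax)]
    sterile = np.clip(slope * (tmax[days] - threshold), 0.0, 1.0)
    return float(np.prod(1.0 - sterile))


def simulate_crop(
    rs: np.ndarray,
    tmax: np.ndarray,
    tmin: np.ndarray,
    transpiration_ratio: np.ndarray,
    pheno: PhenoDates,
    cfg: CropRunConfig,
) -> float:
    """Simulate one season and return yield in t/ha.

    ``rs`` is daily global radiation (MJ m-2), ``transpiration_ratio`` the
    daily ETa/ET0 supply ratio (ignored in potential mode).  The daily loop
    runs from emergence to maturity; deterministic.
    """
    rs = np.asarray(rs, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)

    potential = cfg.water_mode == "potential"
    if potential:
        fw_all = np.ones(len(rs))
    else:
        fw_all = np.clip(np.asarray(transpiration_ratio, dtype=float), 0.0, 1.0)

    tt_all = daily_thermal_time(tmax, tmin, 0.0)
    expansion_rate = cfg.max_lai / cfg.lai_expansion_tt  # LAI per degC day

    lai = 0.0
    biomass = 0.0  # g DM m-2
    sen_rate = None
    for d in range(pheno.emergence_idx, pheno.maturity_idx + 1):
        fw = fw_all[d]
        tt = tt_all[d]
        if d < pheno.anthesis_idx:
            lai = min(cfg.max_lai, lai + expansion_rate * tt * fw)
        else:
            if sen_rate is None:
                # Senesce the canopy present at anthesis over the grain fill.
                tt_grainfill = max(
                    float(np.sum(tt_all[pheno.anthesis_idx:pheno.maturity_idx + 1])),
                    1e-9,
                )
                sen_rate = lai / tt_grainfill
            lai = max(0.0, lai - sen_rate * tt * (2.0 - fw))
        par = 0.5 * rs[d]
        intercepted = par * (1.0 - np.exp(-cfg.extinction_k * lai))
        biomass += cfg.rue * intercepted * fw

    yield_t_ha = biomass * 0.01 * cfg.harvest_index_base  # g/m2 -> t/ha

    if cfg.variant == "drought_sensitive" and not potential:
        yield_t_ha *= drought_grain_factor(transpiration_ratio, pheno)
    elif cfg.variant == "heat_sensitive":
        yield_t_ha *= heat_sterility_factor(tmax, pheno, cfg.heat_sterility_slope)
    return float(yield_t_ha)


def run_yield_set(
    rs: np.ndarray,
    tmax: np.ndarray,
    tmin: np.ndarray,
    transpiration_ratio: np.ndarray,
    pheno: PhenoDates,
    cfg: CropRunConfig = CropRunConfig(),
) -> YieldSet:
    """The four paired runs for one season (shared parameters from ``cfg``)."""
    from dataclasses import replace

    y = simulate_crop(rs, tmax, tmin, transpiration_ratio, pheno,
                      replace(cfg, variant="tolerant", water_mode="potential"))
    yw = simulate_crop(rs, tmax, tmin, transpiration_ratio, pheno,
                       replace(cfg, variant="tolerant", water_mode="rainfed"))
    ywd = simulate_crop(rs, tmax, tmin, transpiration_ratio, pheno,
                        replace(cfg, variant="drought_sensitive", water_mode="rainfed"))
    ywh = simulate_crop(rs, tmax, tmin, transpiration_ratio, pheno,
                        replace(cfg, variant="heat_sensitive", water_mode="rainfed"))
    return YieldSet(y, yw, ywd, ywh)


def _safe_loss(numer, denom):
    """1 - numer/denom with the 0/0 convention of no stress."""
    numer = np.asarray(numer, dtype=float)
    denom = np.asarray(denom, dtype=float)
    ratio = np.divide(numer, denom, out=np.ones_like(numer), where=denom > 0)
    return np.clip(1.0 - ratio, 0.0, 1.0)


def compute_stress_indices(yields: list[YieldSet]) -> StressIndices:
    """Per-year HSI/DSI/WSI with mean and 95th-percentile summaries.

    The 95th percentile uses linear interpolation between order statistics
    (numpy's default convention).  At least 20 retained years are required
    for the percentile to be meaningful.
    """
    if len(yields) < 20:
        raise ValueError("need >= 20 retained years for the 95th percentile")
    y = np.array([ys.y_potential for ys in yields])
    yw = np.array([ys.y_water_limited for ys in yields])
    ywd = np.array([ys.y_drought_sensitive for ys in yields])
    ywh = np.array([ys.y_heat_sensitive for ys in yields])

    hsi = _safe_loss(ywh, yw)
    dsi = _safe_loss(ywd, yw)
    wsi = _safe_loss(yw, y)
    return StressIndices(
        hsi=hsi, dsi=dsi, wsi=wsi,
        hsi_mean=float(hsi.mean()), dsi_mean=float(dsi.mean()),
        wsi_mean=float(wsi.mean()),
        hsi95=float(np.percentile(hsi, 95)),
        dsi95=float(np.percentile(dsi, 95)),
        wsi95=float(np.percentile(wsi, 95)),
    )
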
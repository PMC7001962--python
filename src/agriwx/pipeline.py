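"""Experiment orchestration: sites x ensemble members, end to end.

For every site and every scenario cell (the baseline plus one cell per
change-factor set) the pipeline generates a long synthetic daily series,
derives radiation and reference evapotranspiration, runs the soil water
balance, predicts phenology for each crop season, evaluates the seven
adverse-event detectors and the crop stress model, and summarises the
retained (post-spin-up) seasons.  All randomness flows from one master seed;
each site gets its own deterministic stream, shared by all of that site's
scenario cells so that scenario contrasts are paired (common random numbers)
and a neutral change-factor cell reproduces the baseline exactly.  Cells are
independent and may run in any order with identical results.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import adverse_indices, crop_stress, metforcing, phenology, soilwater, wxgen

__all__ = [
    "SiteConfig",
    "ExperimentConfig",
    "CellResult",
    "ExperimentResult",
    "run_cell",
    "run_experiment",
    "write_outputs",
]

logger = logging.getLogger("agriwx")

#: Days before sowing / after sowing the season slice must cover so that all
#: detector windows (and a worst-case 365-day season) stay in range.
_SLICE_BEFORE = 16
_SLICE_AFTER = 391


@dataclass
class SiteConfig:
    """One study site: location plus either a weather CSV or synthetic knobs."""

    name: str
    latitude: float
    longitude: float = 0.0
    elevation: float = 50.0
    wetness: float = 1.0     # synthetic-site rainfall scaling
    warmth: float = 0.0      # synthetic-site temperature offset, degC
    weather_csv: str | None = None

    def climatology(self) -> wxgen.SiteClimatology:
        if self.weather_csv is not None:
            raw = wxgen.read_weather_csv(self.weather_csv)
            clean, _ = wxgen.qc_series(raw, latitude=self.latitude)
            return wxgen.fit_climatology(clean, latitude=self.latitude)
        return wxgen.synthetic_site_climatology(
            latitude=self.latitude, wetness=self.wetness, warmth=self.warmth
        )


@dataclass
class ExperimentConfig:
    """Full experiment description (see README for the YAML schema)."""

    sites: list[SiteConfig]
    change_factors: list[wxgen.ChangeFactorSet] = field(default_factory=list)
    n_years: int = 300
    spin_up_years: int = 50
    sowing_doy: int = phenology.SOWING_DOY_DEFAULT
    cultivar: phenology.CultivarParams = field(default_factory=phenology.CultivarParams)
    crop_config: crop_stress.CropRunConfig = field(default_factory=crop_stress.CropRunConfig)
    indices_profile: str = "default180"
    stress_profiles: tuple = ("hafren177",)
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50
    master_seed: int = 0

    def __post_init__(self):
        if self.spin_up_years >= self.n_years:
            raise ValueError("spin_up_years must be < n_years")
        for name in (self.indices_profile, *self.stress_profiles):
            if name not in soilwater.SOIL_PROFILES:
                raise ValueError(f"unknown soil profile {name!r}")

    def site_seed(self, site_index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=(self.master_seed, site_index))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sites = [SiteConfig(**s) for s in raw["sites"]]
        cfs: list[wxgen.ChangeFactorSet] = []
        ens = raw.get("ensemble")
        if ens:
            if "csv" in ens:
                cfs = wxgen.read_change_factor_csv(ens["csv"])
            elif "synthetic" in ens:
                syn = dict(ens["synthetic"])
                seed = syn.pop("seed", raw.get("master_seed", 0))
                cfs = wxgen.make_synthetic_ensemble(seed=seed, **syn)
        kwargs = {}
        for key in ("n_years", "spin_up_years", "sowing_doy", "indices_profile",
                    "master_seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stress_profiles" in raw:
            kwargs["stress_profiles"] = tuple(raw["stress_profiles"])
        if "cultivar" in raw:
            kwargs["cultivar"] = phenology.CultivarParams(**raw["cultivar"])
        if "crop" in raw:
            kwargs["crop_config"] = crop_stress.CropRunConfig(**raw["crop"])
        if "angstrom" in raw:
            kwargs["angstrom_a"] = raw["angstrom"].get("a", 0.25)
            kwargs["angstrom_b"] = raw["angstrom"].get("b", 0.50)
        return cls(sites=sites, change_factors=cfs, **kwargs)


@dataclass
class CellResult:
    """Results of one site x scenario cell over the retained seasons."""

    site: str
    scenario: str                       # "baseline" or the change-factor gcm_id
    n_retained: int
    n_failed: int                       # seasons where maturity was not reached
    probabilities: dict                 # event -> fraction of retained years
    stress: dict                        # profile name -> StressIndices
    anthesis_doy_mean: float
    maturity_doy_mean: float
    temperature_rate_sowing_anthesis_mean: float
    temperature_rate_anthesis_maturity_mean: float
    per_year: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    cells: dict = field(default_factory=dict)   # (site, scenario) -> CellResult
    failures: list = field(default_factory=list)

    def scenario_names(self) -> list[str]:
        return ["baseline"] + [cf.gcm_id for cf in self.config.change_factors]

    def ensemble_summaries(self) -> dict:
        """Per-site order statistics of each quantity across ensemble members."""
        from .ensemble_report import ensemble_summary

        out: dict = {}
        members = [cf.gcm_id for cf in self.config.change_factors]
        if not members:
            return out
        for site in self.config.sites:
            cells = [self.cells.get((site.name, m)) for m in members]
            cells = [c for c in cells if c is not None]
            if not cells:
                continue
            entry: dict = {}
            for ev in adverse_indices.EVENT_NAMES:
                entry[f"p_{ev}"] = ensemble_summary(
                    [c.probabilities[ev] for c in cells])
            for prof in self.config.stress_profiles:
                for q in ("hsi_mean", "dsi_mean", "wsi_mean",
                          "hsi95", "dsi95", "wsi95"):
                    entry[f"{prof}.{q}"] = ensemble_summary(
                        [getattr(c.stress[prof], q) for c in cells])
            entry["anthesis_doy"] = ensemble_summary(
                [c.anthesis_doy_mean for c in cells])
            out[site.name] = entry
        return out


def _season_bounds(sow_year: int, sowing_doy: int) -> tuple[int, int, int]:
    sow_idx = sow_year * 365 + sowing_doy - 1
    return sow_idx - _SLICE_BEFORE, sow_idx, sow_idx + _SLICE_AFTER


def run_cell(
    clim: wxgen.SiteClimatology,
    cf: wxgen.ChangeFactorSet | None,
    config: ExperimentConfig,
    seed,
    site_name: str = "site",
    elevation: float = 50.0,
) -> CellResult:
    """Run one site x scenario cell from climatology to summaries.

    ``seed`` feeds the weather generator; passing the same seed with and
    without a change-factor set yields paired (common-random-number) runs.
    """
    scen = cf.gcm_id if cf is not None else "baseline"
    if cf is not None:
        clim = wxgen.apply_change_factors(clim, cf)

    # One extra calendar year so the final season can run to completion.
    series = wxgen.generate_series(clim, config.n_years + 1, seed)
    doy = series["doy"].to_numpy()
    tmax = series["tmax"].to_numpy()
    tmin = series["tmin"].to_numpy()
    precip = series["precip"].to_numpy()
    tmean = (tmax + tmin) / 2.0

    ra, n_dl = metforcing.extraterrestrial_radiation(clim.latitude, doy)
    rs = metforcing.sunshine_to_radiation(
        series["sun_hours"].to_numpy(), ra, n_dl,
        a=config.angstrom_a, b=config.angstrom_b)
    et0 = metforcing.penman_monteith_et0(
        tmax, tmin, rs, clim.latitude, doy, elevation=elevation)

    profiles = {config.indices_profile, *config.stress_profiles}
    traj = {
        name: soilwater.run_water_balance(
            tmean, precip, et0, soilwater.SOIL_PROFILES[name])
        for name in profiles
    }
    idx_traj = traj[config.indices_profile]
    at_fc = idx_traj.at_or_above_fc
    top_sat = idx_traj.relative_saturation_top
    snow_cm = idx_traj.snow_depth_cm
    transp = {
        name: crop_stress.water_stress_factor(traj[name].eta, et0)
        for name in config.stress_profiles
    }

    flags: list[adverse_indices.EventFlags] = []
    yields: dict[str, list[crop_stress.YieldSet]] = {
        name: [] for name in config.stress_profiles}
    rows = []
    n_failed = 0
    for sow_year in range(config.spin_up_years, config.n_years):
        lo, sow_idx, hi = _season_bounds(sow_year, config.sowing_doy)
        sl = slice(lo, hi)
        try:
            pheno = phenology.predict_stages(
                tmax[sl], tmin[sl], sowing_idx=sow_idx - lo,
                sowing_doy=config.sowing_doy, cultivar=config.cultivar)
        except phenology.CropFailureError:
            n_failed += 1
            warnings.warn(
                f"{site_name}/{scen}: maturity not reached in season sown "
                f"year {sow_year}; season excluded", stacklevel=2)
            continue
        cy = adverse_indices.CropYear(
            harvest_year=sow_year + 1,
            tmax=tmax[sl], tmin=tmin[sl], precip=precip[sl],
            at_fc=at_fc[sl], top_saturation=top_sat[sl],
            snow_depth_cm=snow_cm[sl], pheno=pheno,
        )
        fl = adverse_indices.detect_all(cy)
        flags.append(fl)
        row = {"harvest_year": sow_year + 1,
               "anthesis_doy": pheno.anthesis_doy,
               "maturity_doy": pheno.maturity_doy,
               "rate_sowing_anthesis": pheno.temperature_rate_sowing_anthesis,
               "rate_anthesis_maturity": pheno.temperature_rate_anthesis_maturity,
               **fl.as_dict()}
        for prof in config.stress_profiles:
            ys = crop_stress.run_yield_set(
                rs[sl], tmax[sl], tmin[sl], transp[prof][sl], pheno,
                config.crop_config)
            yields[prof].append(ys)
            row.update({
                f"{prof}.Y": ys.y_potential,
                f"{prof}.Yw": ys.y_water_limited,
                f"{prof}.Ywd": ys.y_drought_sensitive,
                f"{prof}.Ywh": ys.y_heat_sensitive,
            })
        rows.append(row)

    probs = adverse_indices.event_probability(flags)
    stress = {
        prof: crop_stress.compute_stress_indices(yields[prof])
        for prof in config.stress_profiles
    }
    per_year = pd.DataFrame(rows)
    for prof in config.stress_profiles:
        si = stress[prof]
        per_year[f"{prof}.HSI"] = si.hsi
        per_year[f"{prof}.DSI"] = si.dsi
        per_year[f"{prof}.WSI"] = si.wsi
    return CellResult(
        site=site_name,
        scenario=scen,
        n_retained=len(flags),
        n_failed=n_failed,
        probabilities=probs,
        stress=stress,
        anthesis_doy_mean=float(per_year["anthesis_doy"].mean()),
        maturity_doy_mean=float(per_year["maturity_doy"].mean()),
        temperature_rate_sowing_anthesis_mean=float(
            per_year["rate_sowing_anthesis"].mean()),
        temperature_rate_anthesis_maturity_mean=float(
            per_year["rate_anthesis_maturity"].mean()),
        per_year=per_year,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full site x scenario factorial.

    A failure in one cell is logged and recorded; the remaining cells still
    run.  Callers (the CLI) exit non-zero when ``result.failures`` is
    non-empty.
    """
    result = ExperimentResult(config=config)
    scenarios: list = [None] + list(config.change_factors)
    for si, site in enumerate(config.sites):
        clim = site.climatology()
        seed = config.site_seed(si)
        for cf in scenarios:
            name = cf.gcm_id if cf is not None else "baseline"
            t0 = time.perf_counter()
            try:
                cell = run_cell(clim, cf, config, seed, site_name=site.name,
                                elevation=site.elevation)
            except Exception as exc:  # noqa: BLE001 - cell isolation by design
                logger.error("cell %s/%s failed: %s", site.name, name, exc)
                result.failures.append((site.name, name, repr(exc)))
                continue
            result.cells[(site.name, name)] = cell
            logger.info("cell %s/%s done in %.1fs", site.name, name,
                        time.perf_counter() - t0)
    return result


def write_outputs(result: ExperimentResult, outdir) -> None:
    """Write per-year CSVs, a summary JSON and a run log under ``outdir``."""
    import json
    from pathlib import Path

    from .ensemble_report import write_summary_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"sites": {}}
    for (site, scen), cell in sorted(result.cells.items()):
        cell.per_year.to_csv(outdir / f"{site}_{scen}_years.csv", index=False)
        entry = summary["sites"].setdefault(site, {})
        entry[scen] = {
            "n_retained": cell.n_retained,
            "n_failed": cell.n_failed,
            "probabilities": {k: v for k, v in cell.probabilities.items()},
            "stress": {
                prof: {q: getattr(si, q) for q in (
                    "hsi_mean", "dsi_mean", "wsi_mean",
                    "hsi95", "dsi95", "wsi95")}
                for prof, si in cell.stress.items()
            },
            "anthesis_doy_mean": cell.anthesis_doy_mean,
            "maturity_doy_mean": cell.maturity_doy_mean,
        }
    summary["ensemble"] = result.ensemble_summaries()
    write_summary_json(summary, outdir / "summary.json")

    cfg = result.config
    log = {
        "master_seed": cfg.master_seed,
        "n_years": cfg.n_years,
        "spin_up_years": cfg.spin_up_years,
        "sowing_doy": cfg.sowing_doy,
        "sites": [s.name for s in cfg.sites],
        "scenarios": result.scenario_names(),
        "indices_profile": cfg.indices_profile,
        "stress_profiles": list(cfg.stress_profiles),
        "cultivar": cfg.cultivar.__dict__,
        "failures": result.failures,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
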
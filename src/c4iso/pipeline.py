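"""End-to-end orchestration: forcing -> photosynthesis -> fractions ->
aggregation -> land discrimination -> attribution -> box model -> reports.

Every stage is a plain function over the library types so it can be run and
tested in isolation; :func:`run_pipeline` chains them, writes stage outputs
with provenance metadata, and emits a manifest (config, seeds, output
hashes) sufficient to regenerate the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .aggregate import (AnnualSeries, annual_weighted_delta, fit_trend,
                        global_aggregate, partition_gpp, uncertainty_band)
from .attribution import DRIVERS, ScenarioSpec, attribute, freeze_driver
from .boxmodel import BoxModelConfig, run as run_boxmodel
from .distribution import compute_fraction_field
from .forcing import (EmissionHistory, ForcingGrid, ForcingSpec, SyntheticTruth,
                      make_emissions, make_forcing, make_observations)
from .isotopes import (TurnoverCueParams, cue_adjusted_fractions,
                       delta_to_small_delta, land_delta13c, match_sites,
                       mixture_regression_slope, predict_soil_d13c, skill_r2)
from .photosynthesis import CellFlux, PhotosynthesisParams, compute_cell_flux

__all__ = [
    "RunConfig", "derive_seed", "land_annual_series", "run_scenarios",
    "build_truth", "evaluate_observations", "boxmodel_experiments",
    "run_pipeline",
]

DELTA_ATM_DEFAULT = -8.0   # permil, modern atmospheric delta13CO2 for conversions


def derive_seed(seed: int, stage: str) -> int:
    """Fan a single run seed out to a stable per-stage seed (< 2**31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    forcing: ForcingSpec = field(default_factory=ForcingSpec)
    params: PhotosynthesisParams = field(default_factory=PhotosynthesisParams)
    turnover: TurnoverCueParams = field(default_factory=TurnoverCueParams)
    share_mode: str = "indicator"
    delta_atm: float = DELTA_ATM_DEFAULT
    run_attribution: bool = True
    run_boxmodel: bool = True
    n_leaf: int = 2000
    n_soil: int = 500
    obs_noise_sd: float = 0.5
    outdir: str = "c4iso_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "forcing" in raw:
            kwargs["forcing"] = ForcingSpec(**raw["forcing"])
        if "params" in raw:
            kwargs["params"] = PhotosynthesisParams(**raw["params"])
        if "turnover" in raw:
            kwargs["turnover"] = TurnoverCueParams(**raw["turnover"])
        for key in ("share_mode", "delta_atm", "run_attribution", "run_boxmodel",
                    "n_leaf", "n_soil", "obs_noise_sd", "outdir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _cell_annual(cellflux: CellFlux, fractions) -> dict:
    """Per-cell annual diagnostics shared by several stages."""
    g3, g4, gtot = partition_gpp(cellflux.gpp_c3_pot, cellflux.gpp_c4_pot,
                                 fractions.f3_tot, fractions.f4_tot)
    # annual Delta weighted by potential GPP: the annual cover fraction
    # cancels inside the year, and the weighting stays defined where F = 0
    d3_ann = annual_weighted_delta(cellflux.delta3, cellflux.gpp_c3_pot)
    d4_ann = annual_weighted_delta(cellflux.delta4, cellflux.gpp_c4_pot)
    return {
        "gpp_c3_ann": np.nansum(g3, axis=1), "gpp_c4_ann": np.nansum(g4, axis=1),
        "gpp_tot_ann": np.nansum(gtot, axis=1),
        "delta3_ann": d3_ann, "delta4_ann": d4_ann,
    }


def land_annual_series(forcing: ForcingGrid, cellflux: CellFlux, fractions,
                       turnover: TurnoverCueParams = TurnoverCueParams()) -> AnnualSeries:
    """Global annual series: F4, pathway GPP (PgC/yr), global Delta3/Delta4,
    and turnover/CUE-weighted land Delta13C with F4 varying and frozen at the
    baseline year. Trends (per year and per ppm CO2) with standard errors."""
    area = forcing.cell_area_m2()
    mask = forcing.valid_mask
    ca = _cell_annual(cellflux, fractions)

    f4_glob, f4_band = uncertainty_band(fractions.f4_tot, area, mask, "mean")
    gpp3 = global_aggregate(ca["gpp_c3_ann"], area, mask, "sum")
    gpp4 = global_aggregate(ca["gpp_c4_ann"], area, mask, "sum")
    gtot, gtot_band = uncertainty_band(ca["gpp_tot_ann"], area, mask, "sum")
    d3 = global_aggregate(ca["delta3_ann"], area, mask, "mean")
    d4 = global_aggregate(ca["delta4_ann"], area, mask, "mean")

    f4h, f3h, f3w = cue_adjusted_fractions(f4_glob, f4_glob[0], turnover)
    d13c_land = land_delta13c(f4h, f3h, f3w, d3, d4, turnover)
    f4h0, f3h0, f3w0 = cue_adjusted_fractions(
        np.full_like(f4_glob, f4_glob[0]), f4_glob[0], turnover)
    d13c_frozen = land_delta13c(f4h0, f3h0, f3w0, d3, d4, turnover)

    table = pd.DataFrame({
        "year": forcing.years, "ca_ppm": forcing.ca_ppm,
        "f4_global": f4_glob, "f4_band": f4_band,
        "gpp_c3": gpp3, "gpp_c4": gpp4, "gpp_tot": gtot, "gpp_tot_band": gtot_band,
        "delta3_global": d3, "delta4_global": d4,
        "d13c_land": d13c_land, "d13c_land_frozen_f4": d13c_frozen,
    })
    trends = {}
    for var in ("f4_global", "gpp_c3", "gpp_c4", "gpp_tot",
                "delta3_global", "delta4_global", "d13c_land",
                "d13c_land_frozen_f4"):
        for cov, tag in ((forcing.years, "per_yr"), (forcing.ca_ppm, "per_ppm")):
            if np.ptp(np.asarray(cov, dtype=float)) == 0:
                continue  # e.g. frozen-ca scenarios have no per-ppm trend
            slope, se, p = fit_trend(table[var].to_numpy(), cov)
            trends[f"{var}_{tag}"] = {"slope": slope, "stderr": se, "p": p}
    return AnnualSeries(table=table, trends=trends)


def run_land(forcing: ForcingGrid, config: RunConfig):
    """Photosynthesis -> fractions -> annual series for one forcing."""
    cellflux = compute_cell_flux(forcing, config.params)
    fractions = compute_fraction_field(cellflux, forcing, config.share_mode)
    series = land_annual_series(forcing, cellflux, fractions, config.turnover)
    return cellflux, fractions, series


def run_scenarios(forcing: ForcingGrid, config: RunConfig,
                  baseline: AnnualSeries,
                  variables=("f4_global", "gpp_c3", "gpp_c4", "gpp_tot", "d13c_land")):
    """Factorial single-driver scenarios plus the driver attribution tables."""
    scen_tables = {}
    for drv in DRIVERS:
        frozen = freeze_driver(forcing, ScenarioSpec(frozen_drivers=(drv,),
                                                     label=f"frozen_{drv}"))
        _, _, series = run_land(frozen, config)
        scen_tables[drv] = series.table
    contrib, summary = attribute(baseline.table, scen_tables, list(variables))
    return contrib, summary, scen_tables


def build_truth(forcing: ForcingGrid, cellflux: CellFlux, fractions,
                delta_atm: float = DELTA_ATM_DEFAULT,
                n_leaf_sites: int = 1000, n_soil_sites: int = 500,
                noise_sd: float = 0.5, seed: int = 0) -> SyntheticTruth:
    """Ground-truth isotope fields and site tables from a model run.

    Leaf truth is the cell-year annual discrimination of the sampled
    pathway (converted to delta13C with ``delta_atm``); soil truth is the
    period-mean fraction-weighted mixture of C3 and C4 plant delta13C.
    """
    rng = np.random.default_rng(seed)
    ca = _cell_annual(cellflux, fractions)
    d3_ann, d4_ann = ca["delta3_ann"], ca["delta4_ann"]
    sd3 = delta_to_small_delta(d3_ann, delta_atm)
    sd4 = delta_to_small_delta(d4_ann, delta_atm)
    soil_truth = predict_soil_d13c(sd3, sd4, fractions.f3_tot, fractions.f4_tot)

    lats, lons = forcing.lat_centers, forcing.lon_centers
    valid = np.argwhere(forcing.valid_mask)
    ny = forcing.n_years

    leaf_rows = []
    for sid in range(n_leaf_sites):
        ilat, ilon = valid[rng.integers(len(valid))]
        iy = int(rng.integers(ny))
        c4_ok = np.isfinite(d4_ann[iy, ilat, ilon]) and fractions.f4_tot[iy, ilat, ilon] > 0
        pathway = "C4" if (c4_ok and rng.random() < 0.5) else "C3"
        tru = (d4_ann if pathway == "C4" else d3_ann)[iy, ilat, ilon]
        if not np.isfinite(tru):
            continue
        leaf_rows.append({
            "site_id": sid, "lat": lats[ilat], "lon": lons[ilon],
            "year": int(forcing.years[iy]), "pathway": pathway,
            "true_Delta": float(tru),
            "true_d13c": float(delta_to_small_delta(tru, delta_atm)),
        })

    soil_rows = []
    for sid in range(n_soil_sites):
        ilat, ilon = valid[rng.integers(len(valid))]
        tru = soil_truth[ilat, ilon]
        if not np.isfinite(tru):
            continue
        soil_rows.append({"site_id": sid, "lat": lats[ilat], "lon": lons[ilon],
                          "true_d13c": float(tru)})

    return SyntheticTruth(
        true_f4=np.array(fractions.f4_tot, copy=True),
        leaf_sites=pd.DataFrame(leaf_rows), soil_sites=pd.DataFrame(soil_rows),
        noise_sd=noise_sd, seed=seed, grid_shape=(forcing.nlat, forcing.nlon))


def evaluate_observations(forcing: ForcingGrid, cellflux: CellFlux, fractions,
                          leaf_obs: pd.DataFrame, soil_obs: pd.DataFrame,
                          delta_atm: float = DELTA_ATM_DEFAULT) -> dict:
    """Model skill against leaf/soil isotope records (nearest-cell matching)."""
    ca = _cell_annual(cellflux, fractions)
    sd3 = delta_to_small_delta(ca["delta3_ann"], delta_atm)
    sd4 = delta_to_small_delta(ca["delta4_ann"], delta_atm)
    soil_pred_grid = predict_soil_d13c(sd3, sd4, fractions.f3_tot, fractions.f4_tot)

    out = {}
    if len(soil_obs):
        ilat, ilon = match_sites(soil_obs["lat"], soil_obs["lon"],
                                 forcing.lat_centers, forcing.lon_centers)
        pred = soil_pred_grid[ilat, ilon]
        out["soil"] = skill_r2(pred, soil_obs["d13c_permil"].to_numpy())
        slope, slope_se = mixture_regression_slope(pred, soil_obs["d13c_permil"])
        out["soil"]["mixture_slope"] = slope
        out["soil"]["mixture_slope_se"] = slope_se
    if len(leaf_obs):
        ilat, ilon = match_sites(leaf_obs["lat"], leaf_obs["lon"],
                                 forcing.lat_centers, forcing.lon_centers)
        iy = np.searchsorted(forcing.years, leaf_obs["year"].to_numpy())
        out["leaf"] = {}
        for pw, d_ann in (("C3", ca["delta3_ann"]), ("C4", ca["delta4_ann"])):
            sel = (leaf_obs["pathway"] == pw).to_numpy()
            if sel.sum() >= 3:
                pred = d_ann[iy[sel], ilat[sel], ilon[sel]]
                out["leaf"][pw] = skill_r2(pred, leaf_obs.loc[sel, "obs_Delta"].to_numpy())
    return out


def boxmodel_experiments(series: AnnualSeries, seed: int = 0,
                         spinup_years: int = 132,
                         total_emissions_pgc: float = 420.0) -> dict[str, pd.DataFrame]:
    """The three box-model configurations, driven by a synthetic exponential
    emission history that ends at the land-series years.

    Returns runs keyed ``constant`` (fixed 18/6 permil discrimination,
    constant F4), ``varying_delta`` (pipeline Delta3/Delta4, constant F4) and
    ``varying_delta_f4`` (pipeline Delta3/Delta4 and F4).
    """
    years_land = series.years
    years = np.arange(years_land[0] - spinup_years, years_land[-1] + 1)
    emis = make_emissions(years, "exponential", total_pgc=total_emissions_pgc,
                          growth_rate=0.025)

    def extend(x):
        x = np.asarray(x, dtype=float)
        return np.concatenate([np.full(spinup_years, x[0]), x])

    d3 = extend(series.table["delta3_global"])
    d4 = extend(series.table["delta4_global"])
    f4 = extend(series.table["f4_global"])
    f4_const = np.full_like(f4, f4[0])

    runs = {}
    cfg = BoxModelConfig(mode="varying_delta_f4", fertilize=(False, True, True),
                         f4_series=f4_const, delta3_series=np.full_like(d3, d3[0]),
                         delta4_series=np.full_like(d4, d4[0]))
    runs["constant"] = run_boxmodel(cfg, emis, years)
    cfg = dataclasses.replace(cfg, delta3_series=d3, delta4_series=d4)
    runs["varying_delta"] = run_boxmodel(cfg, emis, years)
    cfg = dataclasses.replace(cfg, f4_series=f4)
    runs["varying_delta_f4"] = run_boxmodel(cfg, emis, years)
    return runs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write outputs under ``config.outdir``, return the
    manifest (also written as ``manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {
        "forcing": dataclasses.asdict(config.forcing),
        "params": config.params.to_dict(),
        "turnover": dataclasses.asdict(config.turnover),
        "share_mode": config.share_mode, "delta_atm": config.delta_atm,
        "seed": config.seed,
    }, "stages": [], "outputs": {}}

    try:
        spec = dataclasses.replace(config.forcing,
                                   seed=derive_seed(config.seed, "forcing"))
        forcing = make_forcing(spec)
        cio.save_dataset(cio.forcing_to_dataset(forcing), outdir / "forcing.nc")
        manifest["stages"].append("forcing")

        cellflux, fractions, series = run_land(forcing, config)
        cio.save_dataset(cio.cellflux_to_dataset(cellflux, forcing), outdir / "cellflux.nc")
        cio.save_dataset(cio.fractions_to_dataset(fractions, forcing), outdir / "fractions.nc")
        series.to_csv(outdir / "annual_series.csv")
        (outdir / "trends.json").write_text(json.dumps(series.trends, indent=1))
        manifest["stages"] += ["photosynthesis", "fractions", "aggregate"]

        truth = build_truth(forcing, cellflux, fractions, config.delta_atm,
                            noise_sd=config.obs_noise_sd,
                            seed=derive_seed(config.seed, "observations"))
        leaf_obs, soil_obs = make_observations(truth, forcing,
                                               config.n_leaf, config.n_soil)
        cio.write_table(leaf_obs, outdir / "leaf_obs.csv")
        cio.write_table(soil_obs, outdir / "soil_obs.csv")
        skill = evaluate_observations(forcing, cellflux, fractions,
                                      leaf_obs, soil_obs, config.delta_atm)
        (outdir / "evaluation.json").write_text(json.dumps(skill, indent=1))
        manifest["stages"].append("evaluate")

        if config.run_attribution:
            contrib, summary, _ = run_scenarios(forcing, config, series)
            cio.write_table(contrib, outdir / "attribution.csv")
            cio.write_table(summary, outdir / "attribution_summary.csv")
            manifest["stages"].append("attribution")

        if config.run_boxmodel:
            runs = boxmodel_experiments(series, seed=derive_seed(config.seed, "boxmodel"))
            for name, df in runs.items():
                cio.write_table(df, outdir / f"boxmodel_{name}.csv")
            manifest["stages"].append("boxmodel")
    except Exception as exc:  # leave completed stages readable, name the stage
        done = manifest["stages"][-1] if manifest["stages"] else "startup"
        raise RuntimeError(f"pipeline failed after stage {done!r}: {exc}") from exc

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
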
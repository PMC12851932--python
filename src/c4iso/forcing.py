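"""Synthetic gridded forcing, isotope "observations", and emission histories.

Every downstream stage of the pipeline (photosynthesis, C4-fraction mapping,
aggregation, attribution, box model) is exercised against data from this
module, so the generator aims for Earth-like statistical structure on a small
regular grid rather than any particular reanalysis product:

* monthly daytime air temperature with a latitudinal gradient, a seasonal
  cycle that grows with |latitude|, an optional linear warming trend, and
  AR(1) interannual noise;
* vapour-pressure deficit tied to temperature through the saturation vapour
  pressure and a subtropical dry belt;
* PPFD, fAPAR and root-zone soil moisture with plausible latitudinal and
  seasonal structure;
* an annual CO2 ramp (default 341 -> 404 ppm over 35 years, the historical
  1982-2016 range);
* static land-cover fields (tree cover, C3/C4 crops, urban) in [0, 1].

All randomness flows through a single seeded ``numpy.random.Generator`` so
identical specs reproduce identical grids bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ForcingSpec",
    "ForcingGrid",
    "SyntheticTruth",
    "EmissionHistory",
    "make_forcing",
    "make_observations",
    "make_emissions",
    "fill_tree_cover_gaps",
]

EARTH_RADIUS_M = 6.371e6


def saturation_vapour_pressure(t_air_c: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure (Pa) over water, Magnus form."""
    t = np.asarray(t_air_c, dtype=float)
    return 610.94 * np.exp(17.625 * t / (t + 243.04))


@dataclass(frozen=True)
class ForcingSpec:
    """Parameters of the synthetic forcing generator.

    Defaults describe the study conditions used throughout the test suite:
    a 10 x 20 cell domain spanning 60S-60N, 35 years, a linear CO2 ramp from
    341 to 404 ppm, +0.025 K/yr warming and a +0.2 %/yr relative VPD trend.
    """

    nlat: int = 10
    nlon: int = 20
    year_start: int = 1982
    n_years: int = 35
    lat_min: float = -60.0
    lat_max: float = 60.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    # CO2 ramp (ppm); shape "linear" or "exponential"
    ca_start_ppm: float = 341.0
    ca_end_ppm: float = 404.0
    ca_shape: str = "linear"
    # climate trends
    warming_per_yr: float = 0.025          # K / yr
    vpd_trend_per_yr: float = 0.002        # fractional / yr
    theta_trend_per_yr: float = 0.0        # m3 m-3 / yr
    fapar_trend_per_yr: float = 0.0        # fractional / yr (default: no trend)
    # climatology shape
    t_equator: float = 27.0                # annual-mean T at the equator, degC
    t_lat_gradient: float = 0.45           # K per degree |latitude|
    seasonal_amp_base: float = 2.0         # K
    seasonal_amp_per_deg: float = 0.30     # K per degree |latitude|
    # AR(1) interannual noise
    noise_sd_t: float = 0.4                # K
    noise_sd_rel: float = 0.04             # relative, for vpd/fapar/theta/ppfd
    ar1_rho: float = 0.3
    # tree-cover gap simulation (years listed are emitted as NaN)
    missing_tree_years: tuple = ()
    seed: int = 0

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_start + self.n_years)

    def validate(self) -> None:
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.nlat}x{self.nlon}")
        if self.n_years < 1:
            raise ValueError("year range is empty")
        if self.ca_start_ppm <= 0 or self.ca_end_ppm <= 0:
            raise ValueError("CO2 concentrations must be positive")
        if self.ca_shape not in ("linear", "exponential"):
            raise ValueError(f"unknown ca_shape {self.ca_shape!r}")


@dataclass
class ForcingGrid:
    """All gridded monthly/annual drivers for one simulation domain.

    Monthly fields have shape ``(n_years, 12, nlat, nlon)``; annual land-cover
    fields ``(n_years, nlat, nlon)``; ``ca_ppm`` is annual ``(n_years,)``.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    years: np.ndarray
    t_air: np.ndarray          # degC
    vpd: np.ndarray            # Pa, >= 0
    ppfd: np.ndarray           # mol m-2 month-1, >= 0
    fapar: np.ndarray          # 0-1
    theta: np.ndarray          # m3 m-3
    ca_ppm: np.ndarray         # umol mol-1, per year
    elevation: np.ndarray      # m, (nlat, nlon)
    tree_cover: np.ndarray     # 0-1, (n_years, nlat, nlon)
    f_crop_c3: np.ndarray
    f_crop_c4: np.ndarray
    f_urban: np.ndarray
    valid_mask: np.ndarray     # bool, (nlat, nlon)

    @property
    def nlat(self) -> int:
        return len(self.lat_edges) - 1

    @property
    def nlon(self) -> int:
        return len(self.lon_edges) - 1

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def cell_area_m2(self) -> np.ndarray:
        """Cell areas on a spherical Earth (R = 6371 km), shape (nlat, nlon)."""
        lat_r = np.deg2rad(self.lat_edges)
        lon_r = np.deg2rad(self.lon_edges)
        band = EARTH_RADIUS_M**2 * (np.sin(lat_r[1:]) - np.sin(lat_r[:-1]))
        dlon = np.diff(lon_r)
        return band[:, None] * dlon[None, :]

    def area_weights(self) -> np.ndarray:
        """Normalized area weights over valid cells (sum to 1)."""
        w = self.cell_area_m2() * self.valid_mask
        return w / w.sum()

    def copy(self) -> "ForcingGrid":
        return ForcingGrid(**{k: np.array(v, copy=True) for k, v in vars(self).items()})

    def validate(self) -> None:
        for name in ("fapar", "tree_cover", "f_crop_c3", "f_crop_c4", "f_urban"):
            arr = getattr(self, name)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{name} outside [0, 1]")
        for name in ("vpd", "ppfd", "theta"):
            if np.nanmin(getattr(self, name)) < 0:
                raise ValueError(f"{name} has negative values")
        if np.any(self.ca_ppm <= 0):
            raise ValueError("ca_ppm must be strictly positive")
        managed = self.f_crop_c3 + self.f_crop_c4 + self.f_urban
        if np.nanmax(managed) > 1 + 1e-9:
            raise ValueError("crop + urban fractions exceed 1")


@dataclass
class SyntheticTruth:
    """Ground-truth fields behind synthetic isotope observations.

    ``true_f4`` is the per cell-year C4 fraction the observations were built
    from; leaf/soil tables carry per-record truth before noise. Regenerating
    with the same seed reproduces identical fields.
    """

    true_f4: np.ndarray                 # (n_years, nlat, nlon)
    leaf_sites: pd.DataFrame            # site_id, lat, lon, year, pathway, true_d13c, true_Delta
    soil_sites: pd.DataFrame            # site_id, lat, lon, true_d13c
    noise_sd: float
    seed: int
    grid_shape: tuple = ()


@dataclass
class EmissionHistory:
    """Annual fossil emission flux and its isotopic signature."""

    years: np.ndarray
    fossil_flux: np.ndarray             # PgC / yr, >= 0
    fossil_delta13c: np.ndarray         # permil
    atm_delta13c_obs: Optional[np.ndarray] = None

    def validate(self) -> None:
        if np.any(self.fossil_flux < 0):
            raise ValueError("emission fluxes must be non-negative")
        d = np.asarray(self.fossil_delta13c)
        if np.any(d < -40) or np.any(d > 0):
            raise ValueError("fossil delta13C outside [-40, 0] permil")


def _ar1_anomalies(rng: np.random.Generator, rho: float, sd: float,
                   shape_t: int, shape_space: tuple) -> np.ndarray:
    """AR(1)-in-time anomalies, independent across cells; stationary variance sd^2."""
    z = rng.standard_normal((shape_t,) + shape_space)
    out = np.empty_like(z)
    out[0] = z[0]
    c = np.sqrt(1.0 - rho**2)
    for t in range(1, shape_t):
        out[t] = rho * out[t - 1] + c * z[t]
    return sd * out


def _dry_belt(abs_lat: np.ndarray) -> np.ndarray:
    """Subtropical dryness index peaking near |lat| = 25 deg, in [0, 1]."""
    return np.exp(-(((abs_lat - 25.0) / 12.0) ** 2))


def make_forcing(spec: ForcingSpec) -> ForcingGrid:
    """Generate a reproducible synthetic :class:`ForcingGrid` from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nlat, nlon = spec.n_years, spec.nlat, spec.nlon
    years = spec.years

    lat_edges = np.linspace(spec.lat_min, spec.lat_max, nlat + 1)
    lon_edges = np.linspace(spec.lon_min, spec.lon_max, nlon + 1)
    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    abs_lat = np.abs(lat_c)[:, None] * np.ones((1, nlon))

    months = np.arange(12)
    # seasonal phase: peak warmth in July (month index 6) in the north,
    # January in the south
    phase = np.cos(2 * np.pi * (months[None, :, None, None] - 6) / 12.0)
    hemis = np.where(lat_c >= 0, 1.0, -1.0)[None, None, :, None]
    season = phase * hemis

    t_clim = (spec.t_equator - spec.t_lat_gradient * abs_lat)[None, None, :, :]
    amp = (spec.seasonal_amp_base + spec.seasonal_amp_per_deg * abs_lat)[None, None, :, :]
    dt_years = (years - years[0]).astype(float)[:, None, None, None]
    t_anom = _ar1_anomalies(rng, spec.ar1_rho, spec.noise_sd_t, ny, (nlat, nlon))
    t_air = (t_clim + amp * season + spec.warming_per_yr * dt_years
             + t_anom[:, None, :, :])

    dry = _dry_belt(abs_lat)[None, None, :, :]
    rh = np.clip(0.80 - 0.35 * dry, 0.2, 0.95)
    vpd_anom = 1.0 + _ar1_anomalies(rng, spec.ar1_rho, spec.noise_sd_rel, ny, (nlat, nlon))
    vpd = ((1.0 - rh) * saturation_vapour_pressure(t_air)
           * (1.0 + spec.vpd_trend_per_yr * dt_years) * vpd_anom[:, None, :, :])
    vpd = np.clip(vpd, 0.0, None)

    # PPFD: latitude envelope with the same seasonal phase; mol m-2 month-1
    coslat = np.cos(np.deg2rad(abs_lat))[None, None, :, :]
    ppfd_anom = 1.0 + _ar1_anomalies(rng, spec.ar1_rho, spec.noise_sd_rel, ny, (nlat, nlon))
    ppfd = 1150.0 * coslat * (1.0 + 0.45 * season) * ppfd_anom[:, None, :, :]
    ppfd = np.clip(ppfd, 0.0, None)

    # soil moisture: wetter in tropics/high lat, dry belt in subtropics
    th_anom = _ar1_anomalies(rng, spec.ar1_rho, 0.5 * spec.noise_sd_rel, ny, (nlat, nlon))
    theta = (0.12 + 0.18 * (1.0 - dry) + 0.02 * season
             + spec.theta_trend_per_yr * dt_years + th_anom[:, None, :, :])
    theta = np.clip(theta, 0.01, 0.45)

    # fAPAR follows moisture and growing-season temperature
    fp_anom = 1.0 + _ar1_anomalies(rng, spec.ar1_rho, spec.noise_sd_rel, ny, (nlat, nlon))
    green = 1.0 / (1.0 + np.exp(-(t_air - 2.0) / 4.0))
    fapar = ((0.90 - 0.55 * dry) * green
             * (1.0 + spec.fapar_trend_per_yr * dt_years) * fp_anom[:, None, :, :])
    fapar = np.clip(fapar, 0.0, 0.95)

    # CO2 ramp
    frac = dt_years[:, 0, 0, 0] / max(ny - 1, 1)
    if spec.ca_shape == "linear":
        ca_ppm = spec.ca_start_ppm + (spec.ca_end_ppm - spec.ca_start_ppm) * frac
    else:
        ca_ppm = spec.ca_start_ppm * (spec.ca_end_ppm / spec.ca_start_ppm) ** frac

    elevation = np.abs(rng.normal(300.0, 200.0, size=(nlat, nlon)))

    # static land cover (no trend by default): forests where warm and wet,
    # crops in temperate (C3) and warm (C4) bands, small urban fraction
    t_ann = t_clim[0, 0] + 0.0 * abs_lat
    tree = np.clip(0.92 * (1.0 - _dry_belt(np.abs(lat_c))[:, None]) /
                   (1.0 + np.exp(-(t_ann - 5.0) / 5.0)), 0.0, 0.95)
    tree = np.clip(tree + rng.normal(0.0, 0.03, size=(nlat, nlon)), 0.0, 0.95)
    # C3 crops in the temperate belt; C4 crops collocated with the warm dry
    # belt where C4 potential vegetation is found
    temperate = np.exp(-(((np.abs(lat_c) - 45.0) / 12.0) ** 2))[:, None]
    warm = np.exp(-(((np.abs(lat_c) - 24.0) / 10.0) ** 2))[:, None]
    crop_c3 = np.clip(0.10 * temperate + rng.uniform(0, 0.02, (nlat, nlon)), 0, 1)
    crop_c4 = np.clip(0.05 * warm + rng.uniform(0, 0.01, (nlat, nlon)), 0, 1)
    urban = np.full((nlat, nlon), 0.01)
    total = crop_c3 + crop_c4 + urban
    over = total > 1.0
    if np.any(over):  # renormalize the (rare) oversubscribed cells
        crop_c3[over] /= total[over]
        crop_c4[over] /= total[over]
        urban[over] /= total[over]

    tree_cover = np.repeat(tree[None, :, :], ny, axis=0)
    for yr in spec.missing_tree_years:
        idx = int(yr - years[0])
        if 0 <= idx < ny:
            tree_cover[idx] = np.nan
    f_crop_c3 = np.repeat(crop_c3[None, :, :], ny, axis=0)
    f_crop_c4 = np.repeat(crop_c4[None, :, :], ny, axis=0)
    f_urban = np.repeat(urban[None, :, :], ny, axis=0)

    valid_mask = ppfd.mean(axis=(0, 1)) > 0

    grid = ForcingGrid(
        lat_edges=lat_edges, lon_edges=lon_edges, years=years,
        t_air=t_air, vpd=vpd, ppfd=ppfd, fapar=fapar, theta=theta,
        ca_ppm=np.asarray(ca_ppm, dtype=float), elevation=elevation,
        tree_cover=tree_cover, f_crop_c3=f_crop_c3, f_crop_c4=f_crop_c4,
        f_urban=f_urban, valid_mask=valid_mask,
    )
    grid.validate()
    return grid


def fill_tree_cover_gaps(tree_cover: np.ndarray) -> np.ndarray:
    """Fill all-NaN tree-cover years by averaging the previous and subsequent
    years (first/last years fall back to the single available neighbour)."""
    tc = np.array(tree_cover, copy=True)
    ny = tc.shape[0]
    missing = [t for t in range(ny) if np.all(np.isnan(tc[t]))]
    for t in missing:
        prev = next((i for i in range(t - 1, -1, -1) if i not in missing), None)
        nxt = next((i for i in range(t + 1, ny) if i not in missing), None)
        if prev is not None and nxt is not None:
            tc[t] = 0.5 * (tc[prev] + tc[nxt])
        elif prev is not None:
            tc[t] = tc[prev]
        elif nxt is not None:
            tc[t] = tc[nxt]
        else:
            raise ValueError("tree cover missing in every year")
    return tc


def make_observations(truth: SyntheticTruth, forcing: ForcingGrid,
                      n_leaf: int, n_soil: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw noisy leaf and soil isotope records from a known truth.

    Leaf records carry pathway labels, coordinates, year, and
    d13c = truth + Normal(0, noise_sd); soil records carry site coordinates
    and a time-integrated d13C. ``noise_sd = 0`` reproduces truth exactly.
    """
    if n_leaf < 0 or n_soil < 0:
        raise ValueError("n_leaf and n_soil must be >= 0")
    if truth.grid_shape and truth.grid_shape != (forcing.nlat, forcing.nlon):
        raise ValueError("truth grid does not match forcing grid")
    rng = np.random.default_rng(truth.seed)

    leaf_cols = ["site_id", "lat", "lon", "year", "pathway", "d13c_permil",
                 "true_d13c", "true_Delta", "obs_Delta"]
    soil_cols = ["site_id", "lat", "lon", "d13c_permil", "true_d13c"]

    if n_leaf and len(truth.leaf_sites):
        take = rng.integers(0, len(truth.leaf_sites), size=n_leaf)
        leaf = truth.leaf_sites.iloc[take].reset_index(drop=True).copy()
        noise = rng.normal(0.0, truth.noise_sd, size=n_leaf)
        leaf["d13c_permil"] = leaf["true_d13c"] + noise
        # Delta observations inherit the (sign-flipped) same noise through the
        # small-delta -> Delta conversion linearized at the record's truth
        leaf["obs_Delta"] = leaf["true_Delta"] - noise
        leaf["site_id"] = np.arange(n_leaf)
        leaf = leaf[leaf_cols]
    else:
        leaf = pd.DataFrame(columns=leaf_cols)

    if n_soil and len(truth.soil_sites):
        take = rng.integers(0, len(truth.soil_sites), size=n_soil)
        soil = truth.soil_sites.iloc[take].reset_index(drop=True).copy()
        soil["d13c_permil"] = soil["true_d13c"] + rng.normal(
            0.0, truth.noise_sd, size=n_soil)
        soil["site_id"] = np.arange(n_soil)
        soil = soil[soil_cols]
    else:
        soil = pd.DataFrame(columns=soil_cols)
    return leaf, soil


def make_emissions(years: Sequence[int], shape: str = "exponential",
                   total_pgc: Optional[float] = 400.0,
                   delta13c: float = -28.0,
                   growth_rate: float = 0.02,
                   end_flux: Optional[float] = None) -> EmissionHistory:
    """Build a synthetic fossil-fuel emission history.

    ``shape`` is one of ``"zero"``, ``"constant"``, ``"linear"`` (ramp from 0)
    or ``"exponential"``. If ``total_pgc`` is given the flux is scaled so its
    trapezoid-integrated cumulative equals it exactly; a ``"linear"`` ramp may
    instead fix ``end_flux`` (triangle area then sets the total).
    """
    years = np.asarray(years)
    t = (years - years[0]).astype(float)
    if shape == "zero":
        flux = np.zeros_like(t)
    elif shape == "constant":
        flux = np.ones_like(t)
    elif shape == "linear":
        flux = t / max(t[-1], 1.0)
        if end_flux is not None:
            flux = flux * end_flux
            total_pgc = None
    elif shape == "exponential":
        flux = np.exp(growth_rate * t)
    else:
        raise ValueError(f"unknown emission shape {shape!r}")

    if total_pgc is not None:
        if total_pgc < 0:
            raise ValueError("total emissions must be >= 0")
        integral = np.trapezoid(flux, t) if len(t) > 1 else float(flux.sum())
        flux = flux * (total_pgc / integral) if integral > 0 else flux * 0.0

    hist = EmissionHistory(
        years=years, fossil_flux=flux,
        fossil_delta13c=np.full_like(flux, delta13c, dtype=float))
    hist.validate()
    return hist
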
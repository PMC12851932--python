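"""Gridded-array and table IO.

Grids travel as self-describing xarray Datasets with lat/lon/time
dimensions, written as classic NetCDF through xarray's scipy backend; every
variable carries a ``units`` attribute. Tables are plain CSV via pandas;
readers check required columns by name and preserve any extras.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .forcing import ForcingGrid
from .photosynthesis import CellFlux
from .distribution import FractionField

__all__ = [
    "forcing_to_dataset", "dataset_to_forcing",
    "cellflux_to_dataset", "fractions_to_dataset",
    "save_dataset", "load_dataset",
    "write_table", "read_table", "load_f4_map",
]

_MONTH_FIELDS = {
    "t_air": "degC", "vpd": "Pa", "ppfd": "mol m-2 month-1",
    "fapar": "1", "theta": "m3 m-3",
}
_ANNUAL_FIELDS = {
    "tree_cover": "1", "f_crop_c3": "1", "f_crop_c4": "1", "f_urban": "1",
}


def forcing_to_dataset(grid: ForcingGrid) -> xr.Dataset:
    coords = {
        "year": grid.years.astype("int32"),
        "month": np.arange(1, 13, dtype="int32"),
        "lat": grid.lat_centers,
        "lon": grid.lon_centers,
        "lat_edge": grid.lat_edges,
        "lon_edge": grid.lon_edges,
    }
    data = {}
    for name, units in _MONTH_FIELDS.items():
        data[name] = (("year", "month", "lat", "lon"), getattr(grid, name),
                      {"units": units})
    for name, units in _ANNUAL_FIELDS.items():
        data[name] = (("year", "lat", "lon"), getattr(grid, name), {"units": units})
    data["ca_ppm"] = (("year",), grid.ca_ppm, {"units": "umol mol-1"})
    data["elevation"] = (("lat", "lon"), grid.elevation, {"units": "m"})
    data["valid_mask"] = (("lat", "lon"), grid.valid_mask.astype("int8"), {"units": "1"})
    return xr.Dataset(data, coords=coords)


def dataset_to_forcing(ds: xr.Dataset) -> ForcingGrid:
    required = (list(_MONTH_FIELDS) + list(_ANNUAL_FIELDS)
                + ["ca_ppm", "elevation", "valid_mask"])
    for name in required:
        if name not in ds:
            raise ValueError(f"missing required variable {name!r}")
    kwargs = {name: ds[name].values.astype(float) for name in _MONTH_FIELDS}
    kwargs.update({name: ds[name].values.astype(float) for name in _ANNUAL_FIELDS})
    return ForcingGrid(
        lat_edges=ds["lat_edge"].values.astype(float),
        lon_edges=ds["lon_edge"].values.astype(float),
        years=ds["year"].values.astype(int),
        ca_ppm=ds["ca_ppm"].values.astype(float),
        elevation=ds["elevation"].values.astype(float),
        valid_mask=ds["valid_mask"].values.astype(bool),
        **kwargs,
    )


def cellflux_to_dataset(flux: CellFlux, grid: ForcingGrid) -> xr.Dataset:
    units = {"gpp_c3_pot": "gC m-2 month-1", "gpp_c4_pot": "gC m-2 month-1",
             "chi_c3": "1", "chi_c4": "1", "delta3": "permil", "delta4": "permil"}
    data = {k: (("year", "month", "lat", "lon"), getattr(flux, k), {"units": u})
            for k, u in units.items()}
    return xr.Dataset(data, coords={
        "year": grid.years.astype("int32"), "month": np.arange(1, 13, dtype="int32"),
        "lat": grid.lat_centers, "lon": grid.lon_centers})


def fractions_to_dataset(ff: FractionField, grid: ForcingGrid) -> xr.Dataset:
    names = ("share_c4_gpp", "f4_pot", "f4_nat", "f4_crops", "f3_crops",
             "f_urban", "f4_tot", "f3_tot")
    data = {k: (("year", "lat", "lon"), getattr(ff, k), {"units": "1"})
            for k in names}
    ds = xr.Dataset(data, coords={
        "year": grid.years.astype("int32"),
        "lat": grid.lat_centers, "lon": grid.lon_centers})
    ds.attrs["n_clipped"] = int(ff.n_clipped)
    return ds


def save_dataset(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path, engine="scipy")


def load_dataset(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required or []:
        if col not in df.columns:
            raise ValueError(f"table {Path(path).name} missing required column {col!r}")
    return df


def load_f4_map(path, var: str = "f4") -> np.ndarray:
    """Generic reader for an external C4-fraction map in the gridded format."""
    ds = load_dataset(path)
    if var not in ds:
        raise ValueError(f"missing required variable {var!r}")
    return ds[var].values.astype(float)
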
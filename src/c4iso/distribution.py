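"""Annual C3/C4 fraction mapping from pathway-specific potential GPP.

The potential share of C4 plants in total GPP is computed per cell-year from
monthly potential GPP of the two pathways, restricted to the non-tree
fraction of the cell, and converted to a potential C4 cover fraction via the
emergent constraint F4,pot = share / 1.13. Human-managed area (C3 and C4
crops, urban) is removed to obtain the natural C4 fraction, and the total
C4/C3 fractions add crops back:

    F4,nat = F4,pot - (F3,crops + F4,crops) - F_urban        (clipped at 0)
    F4,tot = F4,nat + F4,crops
    F3,tot = 1 - F4,tot
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcing import ForcingGrid, fill_tree_cover_gaps
from .photosynthesis import CellFlux

__all__ = [
    "FractionField",
    "c4_share_of_gpp",
    "f4_potential",
    "f4_natural",
    "total_fractions",
    "compute_fraction_field",
    "harmonize_external_map",
]

SHARE_TO_FRACTION = 1.13   # emergent constraint: F4,pot = share / 1.13


@dataclass
class FractionField:
    """Per cell-year C3/C4 cover fractions and bookkeeping."""

    share_c4_gpp: np.ndarray
    f4_pot: np.ndarray
    f4_nat: np.ndarray
    f4_crops: np.ndarray
    f3_crops: np.ndarray
    f_urban: np.ndarray
    f4_tot: np.ndarray
    f3_tot: np.ndarray
    n_clipped: int = 0


def c4_share_of_gpp(gpp_c3_pot: np.ndarray, gpp_c4_pot: np.ndarray,
                    tree_cover: np.ndarray, mode: str = "indicator") -> np.ndarray:
    """Potential share of C4 plants in total GPP, per cell-year.

    Monthly potential GPP arrays have shape (n_years, 12, nlat, nlon).
    ``share = (1 - tree_cover) * w4`` with the annual C4-advantage weight w4:

    * ``"indicator"`` (default): GPP-weighted fraction of the year in which
      C4 potential GPP exceeds C3 potential GPP — sharp month-level
      competition, mirroring crossover-temperature behaviour;
    * ``"ratio"``: C4 share of summed annual potential GPP.
    """
    g3 = np.asarray(gpp_c3_pot, dtype=float)
    g4 = np.asarray(gpp_c4_pot, dtype=float)
    if g3.ndim != 4 or g3.shape[1] != 12:
        raise ValueError("expected monthly arrays of shape (years, 12, lat, lon)")
    tree = np.asarray(tree_cover, dtype=float)
    if np.nanmin(tree) < 0 or np.nanmax(tree) > 1:
        raise ValueError("tree_cover outside [0, 1]")

    total = np.nansum(g3 + g4, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "indicator":
            wins = (g4 > g3) * (g3 + g4)
            w4 = np.where(total > 0, np.nansum(wins, axis=1) / total, 0.0)
        elif mode == "ratio":
            w4 = np.where(total > 0, np.nansum(g4, axis=1) / total, 0.0)
        else:
            raise ValueError(f"unknown share mode {mode!r}")
    return (1.0 - tree) * w4


def f4_potential(share: np.ndarray) -> np.ndarray:
    """F4,pot = share / 1.13, clipped to [0, 1]."""
    share = np.asarray(share, dtype=float)
    if np.nanmin(share) < 0 or np.nanmax(share) > 1:
        raise ValueError("share outside [0, 1]")
    return np.clip(share / SHARE_TO_FRACTION, 0.0, 1.0)


def f4_natural(f4_pot, f3_crops, f4_crops, f_urban) -> tuple[np.ndarray, int]:
    """Natural C4 fraction after removing managed area; clipped at 0.

    Returns the field and the number of cells where the clip removed actual
    C4 potential (where F4,pot = 0 the subtraction is vacuous and the clip
    merely restores the zero, so those cells are not counted as affected).
    """
    f4p = np.asarray(f4_pot, dtype=float)
    raw = (f4p
           - (np.asarray(f3_crops, dtype=float) + np.asarray(f4_crops, dtype=float))
           - np.asarray(f_urban, dtype=float))
    n_clipped = int(np.sum((raw < 0) & (f4p > 0)))
    return np.clip(raw, 0.0, 1.0), n_clipped


def total_fractions(f4_nat, f4_crops) -> tuple[np.ndarray, np.ndarray]:
    """Total C4 and C3 fractions; F3,tot + F4,tot = 1 exactly."""
    f4_tot = np.clip(np.asarray(f4_nat, dtype=float)
                     + np.asarray(f4_crops, dtype=float), 0.0, 1.0)
    return f4_tot, 1.0 - f4_tot


def compute_fraction_field(cellflux: CellFlux, forcing: ForcingGrid,
                           mode: str = "indicator") -> FractionField:
    """Full fraction pipeline for a forcing grid (tree-cover gaps filled)."""
    tree = fill_tree_cover_gaps(forcing.tree_cover)
    share = c4_share_of_gpp(cellflux.gpp_c3_pot, cellflux.gpp_c4_pot, tree, mode)
    f4_pot = f4_potential(share)
    f4_nat, n_clipped = f4_natural(f4_pot, forcing.f_crop_c3,
                                   forcing.f_crop_c4, forcing.f_urban)
    f4_tot, f3_tot = total_fractions(f4_nat, forcing.f_crop_c4)
    return FractionField(
        share_c4_gpp=share, f4_pot=f4_pot, f4_nat=f4_nat,
        f4_crops=np.array(forcing.f_crop_c4, copy=True),
        f3_crops=np.array(forcing.f_crop_c3, copy=True),
        f_urban=np.array(forcing.f_urban, copy=True),
        f4_tot=f4_tot, f3_tot=f3_tot, n_clipped=n_clipped)


def harmonize_external_map(f4_map: np.ndarray, valid_mask: np.ndarray) -> np.ndarray:
    """Homogenize an external C4 map: on-land missing values become F4 = 0.

    Cells on the valid (vegetated) mask that are NaN are set to 0; off-mask
    cells stay undefined (NaN). The grid shapes must match.
    """
    f4 = np.array(f4_map, dtype=float, copy=True)
    mask = np.asarray(valid_mask, dtype=bool)
    if f4.shape[-2:] != mask.shape:
        raise ValueError(
            f"map grid {f4.shape[-2:]} does not match mask {mask.shape}")
    missing_on_land = np.isnan(f4) & mask
    f4[missing_on_land] = 0.0
    f4[..., ~mask] = np.nan
    return f4
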
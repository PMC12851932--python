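"""GPP partitioning, annual weighting, global aggregation, trends and bands.

Per-cell monthly potential GPP is partitioned by the annual cover fractions
(GPP_C3 = GPP_C3,pot * F3,tot and so on, with GPP_tot their exact sum),
monthly discrimination is GPP-weighted into annual values, and everything is
aggregated to global annual series with spherical cell-area weights
(R = 6371 km). Trends are ordinary least squares on annual values, against
calendar year or annual CO2; no autocorrelation correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AnnualSeries",
    "partition_gpp",
    "annual_weighted_delta",
    "global_aggregate",
    "fit_trend",
    "uncertainty_band",
]

G_TO_PG = 1e-15


@dataclass
class AnnualSeries:
    """Global annual series with trends; thin wrapper over a DataFrame."""

    table: pd.DataFrame                      # one row per year
    trends: dict = field(default_factory=dict)

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def partition_gpp(gpp_c3_pot, gpp_c4_pot, f3_tot, f4_tot):
    """Partition monthly potential GPP by annual cover fractions.

    Returns per cell-month (gpp_c3, gpp_c4, gpp_tot); the total is the exact
    sum of the two pathway fluxes on every cell-month.
    """
    g3p = np.asarray(gpp_c3_pot, dtype=float)
    g4p = np.asarray(gpp_c4_pot, dtype=float)
    f3 = np.asarray(f3_tot, dtype=float)
    f4 = np.asarray(f4_tot, dtype=float)
    if g3p.shape != g4p.shape:
        raise ValueError("potential GPP grids differ in shape")
    if f3.shape != f4.shape or f3.shape != g3p.shape[:1] + g3p.shape[2:]:
        raise ValueError("fraction grids do not match the GPP grid")
    g3 = g3p * f3[:, None]
    g4 = g4p * f4[:, None]
    return g3, g4, g3 + g4


def annual_weighted_delta(delta_monthly, gpp_monthly):
    """GPP-weighted annual discrimination per cell-year (permil).

    Delta_yr = sum_m(Delta_m * GPP_m) / sum_m GPP_m; cells with zero annual
    GPP are undefined (NaN) and excluded from any later aggregation.
    """
    d = np.asarray(delta_monthly, dtype=float)
    g = np.asarray(gpp_monthly, dtype=float)
    if d.shape != g.shape:
        raise ValueError("delta and GPP grids differ in shape")
    total = np.nansum(g, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.nansum(d * g, axis=1) / total
    return np.where(total > 0, out, np.nan)


def global_aggregate(field_annual, cell_area_m2, valid_mask, mode: str = "mean"):
    """Aggregate per-cell annual fields to a global annual series.

    ``mode="sum"`` converts per-area fluxes (gC m-2 yr-1) to PgC yr-1;
    ``mode="mean"`` returns the area-weighted mean. Cells invalid (NaN) in
    any year are excluded in every year so trends compare like with like.
    """
    x = np.asarray(field_annual, dtype=float)
    area = np.asarray(cell_area_m2, dtype=float)
    if np.any(area < 0) or not np.all(np.isfinite(area)):
        raise ValueError("cell areas must be finite and non-negative")
    keep = np.asarray(valid_mask, dtype=bool) & np.all(np.isfinite(x), axis=0)
    if not np.any(keep):
        raise ValueError("no valid cells to aggregate")
    if mode == "sum":
        return np.sum(x[:, keep] * area[keep], axis=1) * G_TO_PG
    if mode == "mean":
        w = area[keep] / area[keep].sum()
        return np.sum(x[:, keep] * w, axis=1)
    raise ValueError(f"unknown aggregation mode {mode!r}")


def fit_trend(y, covariate):
    """OLS trend of an annual series against year or annual CO2.

    Returns ``(slope, stderr, pvalue)``; two-sided t test. The covariate
    must vary (a constant covariate is rejected).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points to fit a trend")
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate with zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


def uncertainty_band(field_annual, cell_area_m2, valid_mask, mode: str = "mean",
                     input_uncertainty_fraction: float = 0.02):
    """95% band per year: 1.96 x spatial SE of the mean/sum, plus a flat
    input-data term of ``input_uncertainty_fraction`` x |global value|.

    For the mean, SE is the area-weighted standard error
    sqrt(sum w_i^2 (x_i - xbar)^2) with normalized weights; for the sum it is
    sd(cell contributions) * sqrt(n). Returns (value, half_width) arrays.
    """
    x = np.asarray(field_annual, dtype=float)
    area = np.asarray(cell_area_m2, dtype=float)
    keep = np.asarray(valid_mask, dtype=bool) & np.all(np.isfinite(x), axis=0)
    value = global_aggregate(x, area, valid_mask, mode)
    xs = x[:, keep]
    if mode == "mean":
        w = area[keep] / area[keep].sum()
        se = np.sqrt(np.sum((w[None, :] * (xs - value[:, None])) ** 2, axis=1))
    else:
        contrib = xs * area[keep] * G_TO_PG
        n = contrib.shape[1]
        se = (np.std(contrib, axis=1, ddof=1) * np.sqrt(n)) if n > 1 else np.zeros(len(value))
    half = 1.96 * se + input_uncertainty_fraction * np.abs(value)
    return value, half
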
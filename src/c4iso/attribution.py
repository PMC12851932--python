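"""Factorial driver attribution.

Each scenario re-runs the full pipeline with one (or more) of the drivers
ca, T_air, VPD, theta held at its baseline-year values — the frozen driver
repeats the baseline year's 12 monthly values (the annual value, for ca) in
every year, preserving seasonality. The contribution of a driver is the
difference baseline(t) - scenario(t) of any global annual variable. fAPAR is
never frozen; it is not one of the four drivers and remains a confound noted
in run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcing import ForcingGrid

__all__ = ["ScenarioSpec", "freeze_driver", "attribute", "DRIVERS"]

DRIVERS = ("ca", "t_air", "vpd", "theta")
_FIELD = {"ca": "ca_ppm", "t_air": "t_air", "vpd": "vpd", "theta": "theta"}


@dataclass(frozen=True)
class ScenarioSpec:
    """Which drivers to freeze, at which baseline year."""

    frozen_drivers: tuple = ()
    baseline_year: int | None = None   # default: first year of the forcing
    label: str = ""

    def validate(self) -> None:
        unknown = set(self.frozen_drivers) - set(DRIVERS)
        if unknown:
            raise ValueError(f"unknown driver(s) {sorted(unknown)}; "
                             f"valid drivers are {DRIVERS}")


def freeze_driver(forcing: ForcingGrid, spec: ScenarioSpec) -> ForcingGrid:
    """Return a forcing copy with the scenario's drivers frozen at baseline."""
    spec.validate()
    out = forcing.copy()
    if not spec.frozen_drivers:
        return out
    y0 = spec.baseline_year if spec.baseline_year is not None else int(forcing.years[0])
    if y0 not in forcing.years:
        raise ValueError(f"baseline year {y0} outside forcing range")
    i0 = int(np.where(forcing.years == y0)[0][0])
    for drv in spec.frozen_drivers:
        name = _FIELD[drv]
        arr = getattr(out, name)
        frozen = np.repeat(arr[i0:i0 + 1], forcing.n_years, axis=0)
        setattr(out, name, frozen)
    return out


def attribute(baseline: pd.DataFrame, scenarios: dict[str, pd.DataFrame],
              variables: list[str], last_n: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-driver contribution series and last-``last_n``-year means.

    ``baseline`` and each scenario table must share the same ``year`` column;
    contribution_d(t) = baseline(t) - scenario_d(t). Returns a tidy frame
    (driver, year, variable, contribution) and a summary of the mean
    contribution over the final ``last_n`` years.
    """
    rows, summary = [], []
    years = baseline["year"].to_numpy()
    for driver, scen in scenarios.items():
        if not np.array_equal(scen["year"].to_numpy(), years):
            raise ValueError(f"scenario {driver!r} years misaligned with baseline")
        for var in variables:
            contrib = baseline[var].to_numpy() - scen[var].to_numpy()
            rows.extend({"driver": driver, "year": int(y), "variable": var,
                         "contribution": float(c)} for y, c in zip(years, contrib))
            summary.append({"driver": driver, "variable": var,
                            "mean_last": float(np.mean(contrib[-last_n:]))})
    return pd.DataFrame(rows), pd.DataFrame(summary)
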
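"""Box model: steady state, bookkeeping identities, isotope mixing, Suess."""

import dataclasses

import numpy as np
import pytest

from c4iso.boxmodel import (BoxModelConfig, compare_to_observed,
                            init_steady_state, run, spin_up_drift, step)
from c4iso.forcing import EmissionHistory, make_emissions


def zero_emissions(n):
    years = np.arange(n)
    return EmissionHistory(years, np.zeros(n), np.full(n, -28.0))


@pytest.fixture(scope="module")
def split_config():
    return BoxModelConfig(delta_c4_const=6.0, fertilize=(False, True, True))


class TestSteadyState:
    def test_zero_emission_run_holds_delta(self, split_config):
        assert spin_up_drift(split_config, 100) < 1e-4

    def test_flux_balance_per_box(self, split_config):
        state = init_steady_state(split_config)
        npp = np.array(split_config.npp0)
        assert np.allclose(state.bio_c / np.array(split_config.tau), npp)

    def test_doubling_npp_doubles_stock(self, split_config):
        cfg2 = dataclasses.replace(split_config,
                                   npp0=tuple(2 * n for n in split_config.npp0))
        s1 = init_steady_state(split_config)
        s2 = init_steady_state(cfg2)
        assert np.allclose(s2.bio_c, 2 * s1.bio_c)


class TestStep:
    def test_zero_emissions_steady_unchanged(self, split_config):
        s0 = init_steady_state(split_config)
        s1 = step(s0, split_config, 0.0, -28.0, split_config.base_deltas(),
                  np.ones(3))
        assert np.isclose(s1.atm_c, s0.atm_c, rtol=1e-12)
        assert abs(s1.atm_delta - s0.atm_delta) < 1e-12

    def test_pure_emission_bookkeeping(self):
        """With exchanges disabled the atmosphere gains exactly E*dt."""
        cfg = BoxModelConfig(npp0=(0.0, 0.0, 0.0), gas_exchange_per_yr=0.0)
        s0 = init_steady_state(cfg)
        s1 = step(s0, cfg, 10.0, -28.0, cfg.base_deltas(), np.ones(3))
        assert np.isclose(s1.atm_c - s0.atm_c, 10.0 * cfg.dt, rtol=1e-12)

    def test_pulse_isotope_mixing(self):
        """A light-carbon pulse moves atmospheric delta by exactly the
        two-member mixing value when exchanges are off."""
        cfg = BoxModelConfig(npp0=(0.0, 0.0, 0.0), gas_exchange_per_yr=0.0,
                             dt=1.0)
        s0 = init_steady_state(cfg)
        pulse = 50.0
        s1 = step(s0, cfg, pulse, -28.0, cfg.base_deltas(), np.ones(3))
        mix = (s0.atm_c * s0.atm_delta + pulse * -28.0) / (s0.atm_c + pulse)
        assert s1.atm_delta < s0.atm_delta
        assert abs(s1.atm_delta - mix) < 1e-9

    def test_negative_reservoir_aborts(self):
        cfg = BoxModelConfig(npp0=(1000.0, 0.0, 0.0), gas_exchange_per_yr=0.0,
                             dt=1.0)
        s0 = init_steady_state(cfg)
        s0.bio_c = np.array([0.1, 0.1, 0.1])
        with pytest.raises(RuntimeError):
            s1 = step(s0, cfg, 0.0, -28.0, cfg.base_deltas(), np.ones(3))
            step(s1, cfg, 0.0, -28.0, cfg.base_deltas(), np.ones(3))


class TestConservation:
    def test_carbon_and_13c_closure(self, split_config):
        years = np.arange(250)
        emis = make_emissions(years, "exponential", total_pgc=500.0,
                              growth_rate=0.02)
        out = run(split_config, emis, years)
        s0 = init_steady_state(split_config)
        rel_c = np.abs(out["carbon_closure"]).max() / s0.total_carbon()
        rel_13 = np.abs(out["m13_closure"]).max() / s0.total_m13()
        assert rel_c < 1e-6 and rel_13 < 1e-6

    def test_suess_direction(self, split_config):
        years = np.arange(150)
        emis = make_emissions(years, "exponential", total_pgc=400.0)
        out = run(split_config, emis, years)
        d = out["d13co2_permil"].to_numpy()
        assert d[-1] < d[0]
        assert np.all(np.diff(d) < 1e-6)  # monotone decline once emitting


class TestModes:
    def _emissions(self, n=150):
        years = np.arange(n)
        return years, make_emissions(years, "exponential", total_pgc=400.0)

    def test_varying_equivalent_to_constant_split(self):
        years, emis = self._emissions()
        n = len(years)
        cfg_v = BoxModelConfig(mode="varying_delta_f4",
                               fertilize=(False, True, True),
                               f4_series=np.full(n, 0.16),
                               delta3_series=np.full(n, 18.0),
                               delta4_series=np.full(n, 6.0))
        cfg_c = BoxModelConfig(mode="constant_delta", delta_c4_const=6.0,
                               fertilize=(False, True, True))
        out_v = run(cfg_v, emis, years)
        out_c = run(cfg_c, emis, years)
        assert np.allclose(out_v["d13co2_permil"], out_c["d13co2_permil"],
                           atol=1e-10)

    def test_increasing_delta_attenuates_suess(self):
        years, emis = self._emissions()
        n = len(years)
        base = dict(mode="varying_delta_f4", fertilize=(False, True, True),
                    f4_series=np.full(n, 0.16),
                    delta4_series=np.full(n, 6.0))
        d3_rising = np.full(n, 18.0)
        d3_rising[-35:] += 0.017 * np.arange(35)
        out_flat = run(BoxModelConfig(**base, delta3_series=np.full(n, 18.0)),
                       emis, years)
        out_rise = run(BoxModelConfig(**base, delta3_series=d3_rising),
                       emis, years)
        decline_flat = out_flat["d13co2_permil"].iloc[-1] - out_flat["d13co2_permil"].iloc[0]
        decline_rise = out_rise["d13co2_permil"].iloc[-1] - out_rise["d13co2_permil"].iloc[0]
        assert abs(decline_rise) < abs(decline_flat)

    def test_co2_driven_mode_attenuates_too(self):
        years, emis = self._emissions()
        out_const = run(BoxModelConfig(mode="constant_delta"), emis, years)
        out_co2 = run(BoxModelConfig(mode="co2_driven_delta"), emis, years)
        d_const = out_const["d13co2_permil"].iloc[-1]
        d_co2 = out_co2["d13co2_permil"].iloc[-1]
        assert d_co2 > d_const

    def test_varying_mode_requires_series(self):
        years, emis = self._emissions(10)
        with pytest.raises(ValueError):
            run(BoxModelConfig(mode="varying_delta_f4"), emis, years)

    def test_emissions_must_cover_years(self, split_config):
        years, emis = self._emissions(10)
        with pytest.raises(ValueError):
            run(split_config, emis, np.arange(5, 20))


class TestCompare:
    def test_identical_series(self):
        import pandas as pd
        df = pd.DataFrame({"year": [2000, 2001], "d13co2_permil": [-8.0, -8.1]})
        assert compare_to_observed(df, df.copy()) == 0.0

    def test_constant_offset(self):
        import pandas as pd
        years = np.arange(2000, 2010)
        a = pd.DataFrame({"year": years, "d13co2_permil": np.linspace(-8, -8.5, 10)})
        b = a.copy()
        b["d13co2_permil"] -= 0.08
        assert np.isclose(compare_to_observed(a, b), 0.08)

    def test_window_and_toy_values(self):
        import pandas as pd
        years = np.arange(2012, 2017)
        pred = pd.DataFrame({"year": years,
                             "d13co2_permil": [-8.5, -8.52, -8.55, -8.57, -8.6]})
        obs = pd.DataFrame({"year": years,
                            "d13co2_permil": [-8.6, -8.65, -8.7, -8.72, -8.78]})
        expected = np.mean(np.array([-8.5, -8.52, -8.55, -8.57, -8.6])
                           - np.array([-8.6, -8.65, -8.7, -8.72, -8.78]))
        assert np.isclose(compare_to_observed(pred, obs, (2012, 2016)), expected)

    def test_no_overlap_rejected(self):
        import pandas as pd
        a = pd.DataFrame({"year": [2000], "d13co2_permil": [-8.0]})
        b = pd.DataFrame({"year": [2010], "d13co2_permil": [-8.0]})
        with pytest.raises(ValueError):
            compare_to_observed(a, b)
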
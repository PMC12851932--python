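"""GPP partitioning, annual weighting, aggregation, trends, bands."""

import numpy as np
import pytest

import oracles
from c4iso.aggregate import (annual_weighted_delta, fit_trend,
                             global_aggregate, partition_gpp,
                             uncertainty_band)


class TestPartition:
    def test_zero_f4(self):
        g3 = np.full((1, 12, 1, 1), 100.0)
        g4 = np.full((1, 12, 1, 1), 80.0)
        c3, c4, tot = partition_gpp(g3, g4, np.ones((1, 1, 1)), np.zeros((1, 1, 1)))
        assert np.all(c4 == 0) and np.array_equal(tot, c3)

    def test_worked_values(self):
        g3 = np.full((1, 12, 1, 1), 100.0)
        g4 = np.full((1, 12, 1, 1), 80.0)
        c3, c4, tot = partition_gpp(g3, g4, np.full((1, 1, 1), 0.75),
                                    np.full((1, 1, 1), 0.25))
        assert np.isclose(c3[0, 0, 0, 0], 75.0)
        assert np.isclose(c4[0, 0, 0, 0], 20.0)
        assert np.isclose(tot[0, 0, 0, 0], 95.0)

    def test_sum_identity_exact(self, land):
        cellflux, fractions, _ = land
        c3, c4, tot = partition_gpp(cellflux.gpp_c3_pot, cellflux.gpp_c4_pot,
                                    fractions.f3_tot, fractions.f4_tot)
        diff = tot - (c3 + c4)
        assert np.nanmax(np.abs(diff)) == 0.0


class TestAnnualDelta:
    def test_constant_gpp_is_plain_mean(self):
        d = np.linspace(10, 21, 12).reshape(1, 12, 1, 1)
        g = np.ones((1, 12, 1, 1))
        assert np.isclose(annual_weighted_delta(d, g)[0, 0, 0], d.mean())

    def test_single_productive_month(self):
        d = np.linspace(10, 21, 12).reshape(1, 12, 1, 1)
        g = np.zeros((1, 12, 1, 1))
        g[0, 3] = 5.0
        assert np.isclose(annual_weighted_delta(d, g)[0, 0, 0], d[0, 3, 0, 0])

    def test_two_month_toy(self):
        d = np.array([10.0, 20.0] * 6).reshape(1, 12, 1, 1)
        g = np.array([1.0, 3.0] * 6).reshape(1, 12, 1, 1)
        assert np.isclose(annual_weighted_delta(d, g)[0, 0, 0],
                          oracles.weighted_delta([10, 20], [1, 3]))

    def test_zero_gpp_undefined(self):
        out = annual_weighted_delta(np.ones((1, 12, 1, 1)), np.zeros((1, 12, 1, 1)))
        assert np.isnan(out[0, 0, 0])

    def test_bounded_by_monthly_extremes(self, land):
        cellflux, _, _ = land
        ann = annual_weighted_delta(cellflux.delta3, cellflux.gpp_c3_pot)
        lo = np.nanmin(cellflux.delta3, axis=1) - 1e-9
        hi = np.nanmax(cellflux.delta3, axis=1) + 1e-9
        ok = np.isfinite(ann)
        assert np.all(ann[ok] >= lo[ok]) and np.all(ann[ok] <= hi[ok])


class TestGlobalAggregate:
    def test_uniform_mean(self):
        x = np.full((3, 2, 2), 7.0)
        area = np.ones((2, 2))
        assert np.allclose(global_aggregate(x, area, np.ones((2, 2), bool)), 7.0)

    def test_single_cell_unit_conversion(self):
        # 500 gC/m2/yr over 2.5e12 m2 -> 500 * 2.5e12 * 1e-15 = 1.25 PgC/yr
        x = np.full((1, 1, 1), 500.0)
        area = np.full((1, 1), 2.5e12)
        out = global_aggregate(x, area, np.ones((1, 1), bool), "sum")
        assert np.isclose(out[0], 500.0 * 2.5e12 * 1e-15)

    def test_sum_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, (4, 3, 3))
        area = rng.uniform(1e11, 1e12, (3, 3))
        mask = np.ones((3, 3), bool)
        s1 = global_aggregate(x, area, mask, "sum")
        s2 = global_aggregate(2 * x, area, mask, "sum")
        assert np.allclose(s2, 2 * s1)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            global_aggregate(np.ones((2, 2, 2)), np.ones((2, 2)),
                             np.zeros((2, 2), bool))


class TestTrend:
    def test_exact_linear(self):
        t = np.arange(2000, 2010)
        slope, se, _ = fit_trend(2.0 * (t - 2000), t)
        assert np.isclose(slope, 2.0, atol=1e-12) and se < 1e-12

    def test_constant_series(self):
        slope, _, _ = fit_trend(np.full(10, 5.0), np.arange(10))
        assert np.isclose(slope, 0.0, atol=1e-12)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(3)
        t = np.arange(35).astype(float)
        y = 0.017 * t + rng.normal(0, 0.01, 35)
        slope, se, p = fit_trend(y, t)
        assert abs(slope - 0.017) < 3 * se and p < 1e-6

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(np.arange(5.0), np.full(5, 380.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestUncertaintyBand:
    def test_zero_variance_only_input_term(self):
        x = np.full((2, 2, 2), 100.0)
        area = np.ones((2, 2))
        value, half = uncertainty_band(x, area, np.ones((2, 2), bool), "mean")
        assert np.allclose(value, 100.0) and np.allclose(half, 2.0)

    def test_zero_input_fraction_zero_band(self):
        x = np.full((2, 2, 2), 100.0)
        value, half = uncertainty_band(x, np.ones((2, 2)), np.ones((2, 2), bool),
                                       "mean", input_uncertainty_fraction=0.0)
        assert np.allclose(half, 0.0)

    def test_four_cell_hand_computation(self):
        x = np.array([[[1.0, 2.0], [3.0, 6.0]]])
        area = np.ones((2, 2))
        value, half = uncertainty_band(x, area, np.ones((2, 2), bool), "mean")
        xbar = 3.0
        se = np.sqrt(sum((0.25 * (v - xbar)) ** 2 for v in (1, 2, 3, 6)))
        assert np.isclose(value[0], xbar)
        assert np.isclose(half[0], 1.96 * se + 0.02 * xbar)

    def test_band_brackets_value(self, forcing, land):
        _, fractions, _ = land
        value, half = uncertainty_band(fractions.f4_tot, forcing.cell_area_m2(),
                                       forcing.valid_mask, "mean")
        assert np.all(half >= 0.02 * np.abs(value) - 1e-15)
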
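"""Photosynthesis core: closed-form oracles, limits, and monotonicity."""

import numpy as np
import pytest

import oracles
from c4iso.photosynthesis import (PhotosynthesisParams, delta13c_c3,
                                  delta13c_c4, gammastar, gpp_potential_c3,
                                  gpp_potential_c4, optimal_chi_c3,
                                  phi0_c4_temperature, soil_moisture_stress)

P = PhotosynthesisParams()


class TestGammastar:
    def test_reference_point(self):
        assert np.isclose(gammastar(25.0, 0.0), P.gammastar25, rtol=1e-12)

    def test_increases_with_temperature(self):
        assert gammastar(35.0, 0.0) > gammastar(25.0, 0.0)

    def test_matches_independent_oracle(self):
        assert np.isclose(gammastar(15.0, 0.0), oracles.gammastar(15.0, 0.0),
                          rtol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            gammastar(np.nan, 0.0)


class TestOptimalChi:
    def test_low_vpd_limit(self):
        # vpd below the 1 Pa numerical floor is clamped, so the limit is the
        # floor value, just short of 1
        chi_floor, _ = optimal_chi_c3(25.0, 1e-9, 40.0, 0.0)
        chi_1pa, _ = optimal_chi_c3(25.0, 1.0, 40.0, 0.0)
        assert chi_floor == chi_1pa
        assert 0.98 < chi_floor < 1.0

    def test_high_vpd_limit(self):
        chi, _ = optimal_chi_c3(25.0, 1e12, 40.0, 0.0)
        assert np.isclose(chi, gammastar(25.0, 0.0) / 40.0, atol=1e-3)

    def test_matches_duplicate_formula(self):
        chi, _ = optimal_chi_c3(25.0, 1000.0, 40.0, 0.0)
        assert np.isclose(chi, oracles.chi_c3(25.0, 1000.0, 40.0, 0.0),
                          rtol=1e-12)

    def test_decreasing_in_vpd(self):
        vpd = np.linspace(100, 4000, 50)
        chi, _ = optimal_chi_c3(25.0, vpd, 40.0, 0.0)
        assert np.all(np.diff(chi) < 0)

    def test_degenerate_ca_flagged(self):
        chi, mj = optimal_chi_c3(25.0, 1000.0, 1.0, 0.0)  # ca below Gamma*
        assert chi == 1.0 and mj == 0.0


class TestGppC3:
    def test_zero_fapar_zero_gpp(self):
        gpp, _, _ = gpp_potential_c3(25.0, 800.0, 1000.0, 0.0, 0.3, 40.0, 0.0)
        assert gpp == 0.0

    def test_well_watered_plateau(self):
        g1, _, _ = gpp_potential_c3(25.0, 800.0, 1000.0, 0.5, 0.30, 40.0, 0.0)
        g2, _, _ = gpp_potential_c3(25.0, 800.0, 1000.0, 0.5, 0.40, 40.0, 0.0)
        assert np.isclose(g1, g2, rtol=1e-12)
        assert soil_moisture_stress(0.35) == 1.0

    def test_linear_in_ppfd(self):
        g1, _, _ = gpp_potential_c3(25.0, 800.0, 1000.0, 0.5, 0.3, 40.0, 0.0)
        g2, _, _ = gpp_potential_c3(25.0, 800.0, 2000.0, 0.5, 0.3, 40.0, 0.0)
        assert np.isclose(g2, 2.0 * g1, rtol=1e-12)

    def test_increasing_in_ca(self):
        ca = np.linspace(25.0, 45.0, 30)
        gpp, _, _ = gpp_potential_c3(25.0, 800.0, 1000.0, 0.5, 0.3, ca, 0.0)
        assert np.all(np.diff(gpp) > 0)


class TestGppC4:
    def test_zero_fapar(self):
        assert gpp_potential_c4(28.0, 1000.0, 0.0) == 0.0

    def test_independent_of_ca_and_theta(self):
        # the call signature carries neither ca nor theta: document by value
        g = gpp_potential_c4(28.0, 1000.0, 0.5)
        assert g > 0

    def test_cold_cutoff(self):
        assert phi0_c4_temperature(-5.0) == 0.0
        assert gpp_potential_c4(-5.0, 1000.0, 0.5) == 0.0


class TestDiscrimination:
    def test_c3_diffusion_limit(self):
        assert np.isclose(delta13c_c3(0.0, 0.0), 4.4)

    def test_c3_carboxylation_limit(self):
        assert np.isclose(delta13c_c3(1.0, 0.0), 28.0)

    def test_c3_worked_value(self):
        assert np.isclose(delta13c_c3(0.7, 0.1), 19.72, atol=1e-12)

    def test_c3_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta13c_c3(1.2, 0.0)
        with pytest.raises(ValueError):
            delta13c_c3(0.5, 1.0)

    def test_c4_diffusion_limit(self):
        assert np.isclose(delta13c_c4(0.0), 4.4)

    def test_c4_worked_value(self):
        assert np.isclose(delta13c_c4(0.45), 1.70, atol=1e-12)

    def test_c4_coefficient_cancellation(self):
        p = PhotosynthesisParams(leakiness=1.0, b4_pep=4.4 - 30.0)
        chi = np.linspace(0, 1, 11)
        assert np.allclose(delta13c_c4(chi, p), 4.4)


def test_monotonicity_sweep():
    """1000 random environments: the documented driver sensitivities hold."""
    rng = np.random.default_rng(0)
    n = 1000
    t = rng.uniform(0, 40, n)
    vpd = rng.uniform(50, 4000, n)
    ca = rng.uniform(25, 45, n)
    z = rng.uniform(0, 3000, n)
    theta = rng.uniform(0.05, 0.45, n)

    chi, _ = optimal_chi_c3(t, vpd, ca, z)
    chi_hi, _ = optimal_chi_c3(t, vpd * 1.2, ca, z)
    assert np.all(chi_hi < chi)

    gs_ca = gammastar(t, z) / ca
    d_lo = delta13c_c3(np.clip(chi - 0.05, 0, 1), gs_ca)
    d_hi = delta13c_c3(np.clip(chi + 0.05, 0, 1), gs_ca)
    assert np.all(d_hi > d_lo)

    gpp, _, _ = gpp_potential_c3(t, vpd, 1000.0, 0.5, theta, ca, z)
    gpp_hi, _, _ = gpp_potential_c3(t, vpd, 1000.0, 0.5, theta, ca * 1.1, z)
    assert np.all(gpp_hi >= gpp)

    g4a = gpp_potential_c4(t, 1000.0, 0.5)
    assert np.all(g4a >= 0)  # and no ca/theta arguments exist to vary


def test_delta_bounds_on_forcing_envelope(land):
    """Delta3 within [a-f, b] and Delta4 finite over the synthetic domain."""
    cellflux, _, _ = land
    d3 = cellflux.delta3[np.isfinite(cellflux.delta3)]
    d4 = cellflux.delta4[np.isfinite(cellflux.delta4)]
    assert d3.min() >= P.a_diff - P.f_photo and d3.max() <= P.b_rub
    assert np.all(np.isfinite(d4)) and d4.size > 0
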
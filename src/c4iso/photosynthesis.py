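"""Light-use-efficiency photosynthesis and carbon-isotope discrimination.

C3 assimilation follows the optimality (least-cost / coordination) treatment:
the ci:ca ratio chi minimizes the combined unit costs of transpiration and
carboxylation,

    chi = Gamma*/ca + (1 - Gamma*/ca) * xi / (xi + sqrt(VPD)),
    xi  = sqrt(beta * (K + Gamma*) / (1.6 * eta*)),

with Gamma* the photorespiratory compensation point, K the effective
Michaelis-Menten coefficient of Rubisco, and eta* the viscosity of water
relative to 25 degC. GPP is then phi0 * Iabs * m' * beta(theta), where
m' applies the Jmax-limitation factor sqrt(1 - (c*/m)^(2/3)) to the CO2
limitation term m = (ci - Gamma*)/(ci + 2 Gamma*), and beta(theta) is a soil
moisture stress ramp applied to C3 only.

C4 assimilation is treated as light- and temperature-limited only
(GPP = phi0_c4(T) * Iabs): the CO2-concentrating mechanism saturates the
carboxylation site, so potential C4 GPP is independent of ca and theta.
A quadratic temperature response gives C4 its warm-climate advantage and a
cold cutoff below which C4 is inactive.

Discrimination:
    Delta3 = a + (b - a) * chi - f * Gamma*/ca          (C3, with photorespiration)
    Delta4 = a + (b4 + phi*b - a) * chi4                (C4, leakiness phi)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .forcing import ForcingGrid

__all__ = [
    "PhotosynthesisParams",
    "CellFlux",
    "air_pressure",
    "gammastar",
    "kmm",
    "viscosity_ratio",
    "optimal_chi_c3",
    "soil_moisture_stress",
    "phi0_c4_temperature",
    "gpp_potential_c3",
    "gpp_potential_c4",
    "delta13c_c3",
    "delta13c_c4",
    "compute_cell_flux",
]

R_GAS = 8.3145           # J mol-1 K-1
T_REF_K = 298.15
P0 = 101325.0            # Pa
MC = 12.011              # g mol-1


@dataclass(frozen=True)
class PhotosynthesisParams:
    """All constants of the photosynthesis/discrimination scheme.

    Reference values follow published P-model practice; isotope endmembers
    are the standard leaf-discrimination constants. Everything is
    configurable; nothing is hard-coded inside the operations.
    """

    phi0_c3: float = 0.085            # mol C / mol photon, at 25 degC
    phi0_c4: float = 0.029            # mol C / mol photon, at 25 degC
    # quadratic quantum-yield temperature responses (a + b T + c T^2),
    # normalized to 1 at 25 degC and clipped at zero; the C4 curve's low
    # root (~2 degC) acts as the cold cutoff below which C4 is inactive
    c3_kphio_coef: tuple = (0.352, 0.0219, -3.4e-4)
    c4_kphio_coef: tuple = (-0.064, 0.03, -4.64e-4)
    phi0_c3_tdep: bool = True
    phi0_c4_tdep: bool = True
    beta_c3: float = 146.0            # unit-cost ratio
    beta_c4: float = 146.0 / 9.0      # for the chi entering Delta4 only
    c_star: float = 0.41              # Jmax-limitation cost
    gammastar25: float = 4.332        # Pa at sea-level pressure
    dha_gammastar: float = 37830.0    # J mol-1
    kc25: float = 39.97               # Pa
    dha_kc: float = 79430.0
    ko25: float = 27480.0             # Pa
    dha_ko: float = 36380.0
    o2_mole_frac: float = 0.20946
    # isotope fractionations (permil)
    a_diff: float = 4.4               # diffusion through stomata
    b_rub: float = 28.0               # net Rubisco term in Delta3
    f_photo: float = 12.0             # photorespiratory fractionation
    b4_pep: float = -7.9              # PEP carboxylation (incl. dissolution)
    b_rub_c4: float = 30.0            # Rubisco fractionation inside the sheath
    leakiness: float = 0.21           # bundle-sheath leakiness phi
    # C3 soil-moisture stress ramp
    theta_wilt: float = 0.05          # m3 m-3
    theta_crit: float = 0.30          # m3 m-3
    vpd_floor: float = 1.0            # Pa

    def validate(self) -> None:
        if not (0.0 < self.phi0_c3 <= 0.125 and 0.0 < self.phi0_c4 <= 0.125):
            raise ValueError("quantum yields must lie in (0, 0.125]")
        if self.beta_c3 <= 0 or self.beta_c4 <= 0:
            raise ValueError("unit-cost ratios must be positive")
        if not 0.0 <= self.leakiness <= 1.0:
            raise ValueError("leakiness must lie in [0, 1]")
        for name in ("a_diff", "b_rub", "f_photo", "b4_pep", "b_rub_c4"):
            if abs(getattr(self, name)) >= 60:
                raise ValueError(f"{name} magnitude implausibly large")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellFlux:
    """Per cell-month potential GPP and discrimination for each pathway."""

    gpp_c3_pot: np.ndarray    # gC m-2 month-1
    gpp_c4_pot: np.ndarray
    chi_c3: np.ndarray        # ci:ca
    chi_c4: np.ndarray
    delta3: np.ndarray        # permil
    delta4: np.ndarray


def air_pressure(z: np.ndarray) -> np.ndarray:
    """Barometric pressure (Pa) at elevation z (m), standard atmosphere."""
    z = np.asarray(z, dtype=float)
    return P0 * (1.0 - 0.0065 * z / 288.15) ** (9.80665 * 0.028963 / (R_GAS * 0.0065))


def _arrhenius(t_air_c: np.ndarray, dha: float) -> np.ndarray:
    tk = np.asarray(t_air_c, dtype=float) + 273.15
    return np.exp(dha / R_GAS * (1.0 / T_REF_K - 1.0 / tk))


def gammastar(t_air_c, z, params: PhotosynthesisParams = PhotosynthesisParams()):
    """Photorespiratory compensation point Gamma* (Pa).

    Arrhenius in temperature, scaled to local pressure through elevation.
    Equals ``gammastar25`` exactly at 25 degC and sea level.
    """
    t = np.asarray(t_air_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite air temperature")
    if np.any(t < -40) or np.any(t > 60):
        raise ValueError("air temperature outside [-40, 60] degC")
    return params.gammastar25 * (air_pressure(z) / P0) * _arrhenius(t, params.dha_gammastar)


def kmm(t_air_c, z, params: PhotosynthesisParams = PhotosynthesisParams()):
    """Effective Michaelis-Menten coefficient K = Kc (1 + pO2/Ko), Pa."""
    kc = params.kc25 * _arrhenius(t_air_c, params.dha_kc)
    ko = params.ko25 * _arrhenius(t_air_c, params.dha_ko)
    po2 = params.o2_mole_frac * air_pressure(z)
    return kc * (1.0 + po2 / ko)


def viscosity_ratio(t_air_c) -> np.ndarray:
    """Viscosity of water relative to 25 degC (Vogel equation)."""
    tk = np.asarray(t_air_c, dtype=float) + 273.15
    visc = np.exp(507.88 / (tk - 149.3))
    visc25 = np.exp(507.88 / (T_REF_K - 149.3))
    return visc / visc25


def optimal_chi_c3(t_air_c, vpd_pa, ca_pa, z,
                   params: PhotosynthesisParams = PhotosynthesisParams(),
                   beta: float | None = None):
    """Least-cost optimal ci:ca ratio and CO2 limitation term for C3.

    Returns ``(chi, mj)``. VPD below the configured floor is clamped (not an
    error); cells with ca <= Gamma* are degenerate and yield chi = 1, mj = 0.
    """
    beta = params.beta_c3 if beta is None else beta
    gs = gammastar(t_air_c, z, params)
    k = kmm(t_air_c, z, params)
    eta = viscosity_ratio(t_air_c)
    vpd = np.maximum(np.asarray(vpd_pa, dtype=float), params.vpd_floor)
    ca = np.asarray(ca_pa, dtype=float)

    xi = np.sqrt(beta * (k + gs) / (1.6 * eta))
    g_over_ca = np.where(ca > 0, gs / np.maximum(ca, 1e-12), 1.0)
    chi = g_over_ca + (1.0 - g_over_ca) * xi / (xi + np.sqrt(vpd))
    degenerate = ca <= gs
    chi = np.where(degenerate, 1.0, np.clip(chi, 0.0, 1.0))

    ci = chi * ca
    mj = (ci - gs) / (ci + 2.0 * gs)
    mj = np.where(degenerate, 0.0, np.clip(mj, 0.0, 1.0))
    return chi, mj


def jmax_limitation(mj, c_star: float) -> np.ndarray:
    """Factor sqrt(1 - (c*/m)^(2/3)); zero where m <= c*."""
    mj = np.asarray(mj, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fac = np.sqrt(np.clip(1.0 - (c_star / np.maximum(mj, 1e-12)) ** (2.0 / 3.0), 0.0, None))
    return np.where(mj > c_star, fac, 0.0)


def soil_moisture_stress(theta, params: PhotosynthesisParams = PhotosynthesisParams()):
    """C3 soil-moisture stress beta(theta) in [0, 1].

    Quadratic ramp x(2 - x) from 0 at the wilting point to a plateau of 1 at
    the critical moisture (zero slope at the plateau).
    """
    x = np.clip((np.asarray(theta, dtype=float) - params.theta_wilt)
                / (params.theta_crit - params.theta_wilt), 0.0, 1.0)
    return x * (2.0 - x)


def _kphio_quadratic(t_air_c, coef: tuple, phi0_25: float) -> np.ndarray:
    a, b, c = coef
    t = np.asarray(t_air_c, dtype=float)
    shape = (a + b * t + c * t * t) / (a + 25.0 * b + 625.0 * c)
    return phi0_25 * np.clip(shape, 0.0, None)


def phi0_c4_temperature(t_air_c, params: PhotosynthesisParams = PhotosynthesisParams()):
    """C4 quantum yield: published quadratic peak curve, zero (C4 inactive)
    below the cold cutoff where the quadratic crosses zero."""
    if not params.phi0_c4_tdep:
        return np.broadcast_to(np.float64(params.phi0_c4),
                               np.shape(np.asarray(t_air_c, dtype=float)))
    return _kphio_quadratic(t_air_c, params.c4_kphio_coef, params.phi0_c4)


def _phi0_c3(t_air_c, params: PhotosynthesisParams):
    if not params.phi0_c3_tdep:
        return np.broadcast_to(np.float64(params.phi0_c3),
                               np.shape(np.asarray(t_air_c, dtype=float)))
    return _kphio_quadratic(t_air_c, params.c3_kphio_coef, params.phi0_c3)


def gpp_potential_c3(t_air_c, vpd_pa, ppfd, fapar, theta, ca_pa, z,
                     params: PhotosynthesisParams = PhotosynthesisParams()):
    """Potential C3 GPP (gC m-2 month-1) = MC phi0 Iabs m' beta(theta)."""
    chi, mj = optimal_chi_c3(t_air_c, vpd_pa, ca_pa, z, params)
    m_prime = mj * jmax_limitation(mj, params.c_star)
    iabs = np.asarray(fapar, dtype=float) * np.asarray(ppfd, dtype=float)
    gpp = MC * _phi0_c3(t_air_c, params) * iabs * m_prime * soil_moisture_stress(theta, params)
    return gpp, chi, mj


def gpp_potential_c4(t_air_c, ppfd, fapar,
                     params: PhotosynthesisParams = PhotosynthesisParams()):
    """Potential C4 GPP (gC m-2 month-1): light- and temperature-limited only,
    independent of ca and soil moisture by construction."""
    iabs = np.asarray(fapar, dtype=float) * np.asarray(ppfd, dtype=float)
    return MC * phi0_c4_temperature(t_air_c, params) * iabs


def delta13c_c3(chi, gammastar_over_ca,
                params: PhotosynthesisParams = PhotosynthesisParams()):
    """C3 discrimination Delta3 = a + (b - a) chi - f Gamma*/ca (permil)."""
    chi = np.asarray(chi, dtype=float)
    g = np.asarray(gammastar_over_ca, dtype=float)
    if np.any((chi < 0) | (chi > 1)):
        raise ValueError("chi outside [0, 1]")
    if np.any((g < 0) | (g >= 1)):
        raise ValueError("Gamma*/ca outside [0, 1)")
    return (params.a_diff + (params.b_rub - params.a_diff) * chi
            - params.f_photo * g)


def delta13c_c4(chi_c4, params: PhotosynthesisParams = PhotosynthesisParams()):
    """C4 discrimination Delta4 = a + (b4 + phi b - a) chi4 (permil)."""
    chi = np.asarray(chi_c4, dtype=float)
    if np.any((chi < 0) | (chi > 1)):
        raise ValueError("chi_c4 outside [0, 1]")
    slope = params.b4_pep + params.leakiness * params.b_rub_c4 - params.a_diff
    return params.a_diff + slope * chi


def compute_cell_flux(forcing: ForcingGrid,
                      params: PhotosynthesisParams = PhotosynthesisParams()) -> CellFlux:
    """Run the per cell-month photosynthesis scheme on a full forcing grid."""
    params.validate()
    z = forcing.elevation[None, None, :, :]
    ca_pa = (forcing.ca_ppm[:, None, None, None] * 1e-6) * air_pressure(z)

    gpp3, chi3, _ = gpp_potential_c3(
        forcing.t_air, forcing.vpd, forcing.ppfd, forcing.fapar,
        forcing.theta, ca_pa, z, params)
    gpp4 = gpp_potential_c4(forcing.t_air, forcing.ppfd, forcing.fapar, params)

    chi4, _ = optimal_chi_c3(forcing.t_air, forcing.vpd, ca_pa, z, params,
                             beta=params.beta_c4)
    gs = gammastar(forcing.t_air, z, params)
    g_over_ca = np.clip(gs / ca_pa, 0.0, 1.0 - 1e-12)
    d3 = delta13c_c3(chi3, g_over_ca, params)
    d4 = delta13c_c4(chi4, params)

    mask = forcing.valid_mask[None, None, :, :]
    nanify = lambda a: np.where(mask, a, np.nan)
    return CellFlux(gpp_c3_pot=nanify(gpp3), gpp_c4_pot=nanify(gpp4),
                    chi_c3=nanify(chi3), chi_c4=nanify(chi4),
                    delta3=nanify(d3), delta4=nanify(d4))
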
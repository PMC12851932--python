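# Methods

This note documents the models implemented in `c4iso`, their assumptions,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical choices that matter
for reproducing its outputs. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Photosynthesis and discrimination (`c4iso.photosynthesis`)

**C3 pathway.** The light-use-efficiency formulation follows the optimality
(P-model) tradition. The ci:ca ratio χ minimizes the combined unit costs of
maintaining transpiration and carboxylation capacity:

    χ  = Γ*/ca + (1 − Γ*/ca) · ξ/(ξ + √D),   ξ = √( β (K + Γ*) / (1.6 η*) )

with D the vapour-pressure deficit (Pa), β = 146 the unit-cost ratio,
Γ* the photorespiratory compensation point and K the effective
Michaelis–Menten coefficient of Rubisco, both Arrhenius functions of
temperature (Γ*₂₅ = 4.332 Pa at sea level, ΔHa = 37.83 kJ mol⁻¹;
Kc₂₅ = 39.97 Pa, ΔHa = 79.43 kJ mol⁻¹; Ko₂₅ = 27 480 Pa,
ΔHa = 36.38 kJ mol⁻¹) scaled to local pressure through elevation
(standard-atmosphere barometric formula). η* is the viscosity of water
relative to 25 °C, computed from the Vogel equation
η ∝ exp(507.88 K / (T − 149.3 K)); over 0–40 °C this agrees with the full
Huber correlation to better than 1 %, which is far below the sensitivity of
any downstream quantity.

GPP per cell-month is

    GPP_C3,pot = Mc · φ0,C3(T) · fAPAR · PPFD · m′ · β(θ)

with m = (ci − Γ*)/(ci + 2Γ*), the Jmax-limitation factor
m′ = m √(1 − (c*/m)^(2/3)), c* = 0.41 (m ≤ c* gives zero), and a soil-
moisture stress ramp β(θ) = x(2 − x), x = clip((θ − θ_w)/(θ_c − θ_w), 0, 1),
with wilting point θ_w = 0.05 and critical moisture θ_c = 0.30 m³ m⁻³.
Moisture and CO₂ stress act on C3 only — the model's central structural
assumption is that elevated CO₂ and water stress matter for C3
photosynthesis while C4 is insulated by its CO₂-concentrating mechanism.

**C4 pathway.** Potential C4 GPP is light- and temperature-limited only:
GPP_C4,pot = Mc · φ0,C4(T) · fAPAR · PPFD, independent of ca and θ by
construction.

**Quantum-yield temperature dependence.** Both pathways use published
quadratic peak curves, normalized to 1 at 25 °C:
φ ∝ 0.352 + 0.0219 T − 3.4e-4 T² for C3 and
φ ∝ −0.064 + 0.03 T − 4.64e-4 T² for C4 (the C4 quadratic's low root near
2 °C is the cold cutoff below which C4 is inactive). Reference values are
φ0,C3 = 0.085 and φ0,C4 = 0.029 mol C (mol photon)⁻¹ at 25 °C, which place
the well-watered C3/C4 crossover near 22 °C at present-day CO₂ — consistent
with the classical crossover-temperature picture — dropping to ~15 °C under
strong moisture stress. An earlier design draft made only the C4 yield
temperature-dependent; that configuration hands warming entirely to C4 and
largely cancels the CO₂-driven F₄ decline, which is why the paired published
curves are the default. Both dependences can be switched off
(`phi0_c3_tdep`, `phi0_c4_tdep`).

**Discrimination.**

    Δ3 = a + (b − a) χ − f Γ*/ca          a = 4.4‰, b = 28‰, f = 12‰
    Δ4 = a + (b4 + φ b − a) χ4            b4 = −7.9‰, φ = 0.21, b = 30‰

χ₄ uses the same least-cost expression with β_C4 = 146/9 (χ₄ ≈ 0.4–0.5 in
warm climates, giving Δ₄ ≈ 1.5–3‰). These endmember constants are the
standard leaf-discrimination values; none are printed in a single canonical
source so all are configurable. Mesophyll conductance, nitrogen effects and
post-photosynthetic fractionation are out of scope.

**Numerical guards.** VPD is floored at 1 Pa (χ would otherwise hit the
singular χ = 1 limit); cells with ca ≤ Γ* are degenerate and return χ = 1,
m = 0, hence zero GPP.

## 2. C4-fraction mapping (`c4iso.distribution`)

The annual potential C4 share of GPP per cell is
share = (1 − tree_cover) · w4. Two selectable constructions of the annual
advantage weight w4 are provided: **indicator** (default) — the GPP-weighted
fraction of the year in which C4 potential GPP exceeds C3 potential GPP,
giving sharp crossover behaviour — and **ratio** — the C4 share of summed
annual potential GPP. The share converts to a cover fraction through the
emergent constraint F₄,pot = share / 1.13.

Managed land is removed exactly as the fraction bookkeeping prescribes,
F₄,nat = F₄,pot − (F₃,crops + F₄,crops) − F_urban, clipped at zero. The
subtraction is vacuous wherever F₄,pot = 0 (any crops in a fully C3 cell
drive it negative); the reported `n_clipped` therefore counts only cells
where the clip removed nonzero C4 potential, the only places it can affect
results. Totals are F₄,tot = F₄,nat + F₄,crops and F₃,tot = 1 − F₄,tot —
the identity holds to machine precision because F₃,tot is defined by
subtraction. External comparison maps are harmonized by setting on-land
missing values to F₄ = 0 and leaving off-mask cells undefined.

Missing tree-cover years are filled by averaging the previous and
subsequent available years.

## 3. Aggregation, trends, uncertainty (`c4iso.aggregate`)

Monthly potential GPP is partitioned by the annual cover fractions
(GPP_C3 = GPP_C3,pot · F₃,tot etc.; the total is the exact sum). Annual
discrimination per cell is the GPP-weighted mean of the monthly values;
because the cover fraction is constant within a year it cancels in the
weighting, so the implementation weights by potential GPP, which keeps the
annual value defined where F = 0. Cells with zero annual GPP are undefined
and excluded; a cell excluded in any year is excluded in every year so that
trends compare a fixed cell set.

Global sums use spherical cell areas (R = 6371 km,
area = R²·Δλ·(sin φ₂ − sin φ₁)) and the gC → PgC factor 1e-15; global means
are area-weighted. Trends are ordinary least squares on annual values with
two-sided t tests and no autocorrelation correction (flagged in the trends
metadata by construction of the method); per-ppm trends regress on annual
CO₂ directly (the alternative — per-year slope divided by mean CO₂ growth —
is available by dividing the two reported slopes). The 95 % band per year is
1.96 × the spatial standard error of the mean (√Σw²(x−x̄)² with normalized
area weights) or of the sum (sd of cell contributions × √n), plus a flat
input-uncertainty term of 2 % of the global value.

## 4. Land Δ¹³C (`c4iso.isotopes`)

The land biosphere is three components — C4 herbaceous, C3 herbaceous,
C3 woody — with turnover times τ = (2.4, 24.4, 299.4) yr and carbon-use
efficiencies CUE = (0.41, 0.46, 0.40). Component fractions relax from the
baseline year toward the current year through CUE,
f = F_t0 − (F_t0 − F_t)·CUE, and land discrimination is

    Δ13C = (f4 Δ4 τ4 + f3h Δ3 τ3h + f3w Δ3 τ3w) / (τ4 + τ3h + τ3w).

The denominator is deliberately the plain sum of turnover times — the
expression does not reduce to Δ3 when f3 = 1 unless every f = 1 — because
that is the printed form of the weighting; a normalized variant (denominator
Σf·τ) is available behind the `normalized` flag for sensitivity analysis.
Both C3 components relax from the full F₃,tot by default; an optional
`woody_share` argument (e.g. tree cover) splits the C3 pool first.

Plant δ¹³C follows from discrimination exactly:
δ_plant = (δ_atm − Δ)/(1 + Δ/1000), with the exact inverse provided. The
soil predictor is the equal-year mean over the simulation period of the
fraction-weighted mixture F₃δ₃ + F₄δ₄ — soil organic matter integrates over
years, and additional fractionation within the soil is assumed negligible.
Equal-year (rather than GPP-weighted) averaging is the design choice; with
the fraction weighting already inside the mixture the difference is second
order. Site matching uses the nearest grid cell by great-circle distance.
Skill is the squared Pearson correlation (undefined and reported as NaN when
either vector is constant), with bias and SD-ratio diagnostics and an OLS
mixture slope of observed on predicted.

## 5. Attribution (`c4iso.attribution`)

Each scenario freezes a subset of {ca, T_air, VPD, θ} at the baseline year's
twelve monthly values (annual value for ca), preserving seasonality, and
re-runs the full pipeline including F₄ recomputation. The contribution of a
driver is baseline(t) − scenario(t). fAPAR is never frozen — it is not one
of the four drivers — and remains a confound noted here. Contributions are
near- but not exactly additive; the interaction residual is a reported
diagnostic, not an assumption.

## 6. Carbon-cycle box model (`c4iso.boxmodel`)

One well-mixed atmosphere (2.124 PgC ppm⁻¹), the three biosphere boxes of
§4, and a box-diffusion ocean: a 75 m mixed layer plus 42 deep layers to
3800 m (43 ocean boxes), ocean area 3.62e14 m², uniform preindustrial DIC
2.05 mol m⁻³, eddy diffusivity 4000 m² yr⁻¹, buffer (Revelle) factor 10,
gross gas exchange at 1/7.5 yr⁻¹ of atmospheric carbon, and kinetic
fractionations of −2‰ (air→sea) and −10‰ (sea→air). These ocean constants
are the conventional box-diffusion calibration; none are contributed by this
package and all sit in `BoxModelConfig`, with `compare_to_observed`
available as a calibration target against any supplied δ¹³CO₂ series.

Biosphere NPP responds to CO₂ logarithmically,
NPP_i = npp0_i·scale_i·(1 + β ln(ca/ca0)) with β = 0.4; fertilization is
disabled for the C4 box in the C4/C3-split configurations since CO₂
fertilization acts on C3 photosynthesis only. Preindustrial NPP is
npp0 = (9, 25, 5) PgC yr⁻¹, chosen so the steady stocks NPP·τ = (21.6, 610,
1497) PgC give a realistic ~2100 PgC land reservoir with the C4 box small
and fast. Respiration returns bio_c/τ at the box's current mean δ
(well-mixed reservoir assumption).

Isotopes use the linearized delta-mass bookkeeping m13 = C(1 + δ/1000);
every internal flux deposits exactly the delta-mass it withdraws
(photosynthesis carries δ_atm − Δ_box, air–sea gross fluxes carry the source
δ plus the kinetic fractionation, respiration and ocean diffusion carry the
source δ), so total carbon and delta-mass are conserved to float roundoff —
the conservation tests check the genuine bookkeeping, not a tolerance
band. The preindustrial steady state is constructed analytically (bio stocks
NPP·τ with δ = δ_atm0 − Δ; uniform-DIC ocean with δ = δ_atm0 + ε_as − ε_sa)
and is an exact fixed point of the integrator.

Three modes: `constant_delta` (fixed 18‰, optionally 6‰ for the C4 box);
`co2_driven_delta` (Δ(t) = Δ0 + 0.014‰ ppm⁻¹ × (ca − ca0)); and
`varying_delta_f4` (annual Δ₃/Δ₄/F₄ series from the land pipeline, with box
NPP scaled by the CUE-adjusted component fractions relative to their
baseline values).

**Integration.** Explicit Euler with substep dt = 0.05 yr. The step was
sized from the Euler error estimate for multi-century runs so that halving
it changes δ¹³CO₂ trajectories by well under 1e-3‰ (measured ≈ 3e-4‰ over
250 yr); the convergence check is part of the acceptance suite. The fastest
internal timescale (interlayer diffusion, ~1 yr⁻¹) keeps the scheme stable
with a wide margin.

## 7. Synthetic forcing and observations (`c4iso.forcing`)

The generator produces Earth-like statistical structure on a small regular
grid (default 10 × 20 cells over 60°S–60°N, 35 years, all land): a linear
latitudinal temperature gradient (27 °C at the equator, −0.45 K per degree)
with seasonality growing poleward, VPD tied to temperature through the
Magnus saturation vapour pressure and a subtropical dry belt (relative
humidity minimum near |lat| = 25°), PPFD with a cosine-latitude envelope,
soil moisture and fAPAR following the moisture pattern, static tree cover
(wet warm cells), C3 crops in the temperate belt and C4 crops collocated
with the warm dry belt (consistent with where C4 potential vegetation
occurs), and a linear 341→404 ppm CO₂ ramp. Trends: +0.025 K yr⁻¹ warming
and a +0.2 % yr⁻¹ relative VPD trend (a slow relative-humidity decline on
top of the warming-driven saturation increase); fAPAR has no trend by
default (greening is deliberately excluded as a confound, configurable).
Interannual noise is AR(1) in time (ρ = 0.3), independent across cells and
fields. All randomness flows through one seeded generator; identical
spec + seed reproduces grids bit-for-bit.

What it does **not** emulate: real land/ocean geography (every cell is
vegetated land, so global totals scale with the domain, not the Earth —
GPP sums near 1000 PgC yr⁻¹ are a property of the all-land band);
spatially correlated weather; ENSO-like modes; land-use change; observed
CO₂ interannual variability. Passing tests therefore demonstrate the
mechanisms and the bookkeeping, not quantitative agreement with the
historical record, whose reproduction requires the real gridded forcings.

A consequence worth stating plainly: in this synthetic world the global Δ₃
trend is approximately zero (the warming-driven χ increase is offset by the
warming- and trend-driven VPD increase and the photorespiratory term), so
the land Δ¹³C trend is carried almost entirely by the F₄ decline — the
varying-vs-frozen-F₄ contrast that the acceptance suite checks — rather
than by per-plant C3 physiology.

Synthetic observations are drawn from model truth: leaf records sample
cell-years and pathways (δ¹³C = truth + N(0, 0.5‰); ~2000 records, the
scale of real leaf compilations), soil records sample the period-mean
mixture per cell (500 sites). Known-truth recovery (soil R², mixture slope,
leaf bias) is the package's evaluation harness; with zero noise the
observations equal truth exactly.

## 8. Reproducibility

A single run seed fans out to per-stage seeds through
`SeedSequence([seed, crc32(stage)])`. The pipeline manifest records the
full configuration, seeds and SHA-256 hashes of every output; the same
configuration and seed regenerate hash-identical outputs. Gridded outputs
are self-describing NetCDF (classic format via the scipy backend) with
units on every variable; tables are plain CSV.

## Known limitations

- The C4 χ and light-use equations are implementer choices within the
  optimality family (the pathway-specific calibration they stand in for is
  not public); they are flagged in the configuration and easily replaced.
- Eq.-style land Δ¹³C uses a fixed global turnover triplet; τ and CUE in
  reality vary with climate and disturbance.
- OLS trends carry no autocorrelation correction; with AR(1) noise the
  standard errors are mildly optimistic.
- The box model has no ocean biology, no land-use emissions, and a single
  well-mixed atmosphere; it is a mechanism demonstrator, not an ESM.
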
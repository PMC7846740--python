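# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic campaign does and does not
emulate, and the numerical details a user extending the package should
know. It states no result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Heat-ratio sap flow

The heat-pulse velocity is `Vh = (k/x)·ln(v1/v2)·3600` cm/h with a nominal
wood thermal diffusivity `k = 2.5e-3 cm²/s` and heater-probe spacing
`x = 0.5 cm`. The log-ratio form is antisymmetric, so reverse (negative)
flow is representable; samples with a non-positive temperature rise leave
the ratio undefined and are excluded with a logged count.

**Wound correction.** Drilling kills a band of conducting tissue, biasing
`Vh` low. We apply `Vc = a + b·Vh + c·Vh²` with coefficients looked up (and
linearly interpolated) by wound width over 0.17–0.30 cm; widths outside the
table raise an error naming the supported range. The shipped defaults
follow the published form for ~2 mm drill holes — multiplicative-dominant
(`b` ≈ 1.7–2.1, small positive `c`), monotone, and inflating (`Vc ≥ Vh` for
`Vh` in (0, 60] cm/h, a property under test). Field studies should
substitute their own calibration via the `coefficients` argument; the
correction is applied to |Vh| with the sign restored. By default the
corrected `Vh` is used directly as sap flux density; wood-property
corrections (density, moisture, specific heats) are out of scope because
no wood-property measurements are part of the input contract.

**Radial integration.** With thermocouples at 0.8 and 1.1 cm below the
cambium, the sapwood band (cambium to visually determined sapwood depth)
is split at the midpoint between probe depths into concentric annuli;
each annulus carries its probe's velocity and the annuli are rescaled so
their total matches the measured sapwood area when one is supplied. Flow
is `Σ_depth v_d · A_d · 1e-3` L/h. With one probe the whole sapwood area
is used.

**Allometry.** Sapwood area vs stem diameter (at 60 cm height) is an
ordinary least-squares line; predictions are clamped positive. Degenerate
designs (< 3 pairs, zero diameter spread) are rejected.

**Daily aggregation.** Timestamps are interval-ending local time; the
midnight stamp closes the previous day. Gaps ≤ 2 h are linearly
interpolated; days with more than 20% of half-hours missing (QC < 0.8)
are dropped and counted. Daily volume is `Σ flow·Δt`; the depth
equivalent divides by canopy area (2 m² default), since 1 L/m² ≡ 1 mm.
Negative daily totals (sustained reverse flow) are retained in the series
but the stand rate is floored at zero before upscaling — reverse flow is
physical but cannot credit water back to the region.

**Habitat/seasonal/stand summaries.** Per-tree period means come first;
habitat statistics are unweighted means ± SD across trees (a single tree
reports SD 0 with a flag). Seasons default to dry = Jan–Mar and rainy =
Jul–Sep; empty windows are flagged, not errors. Stand transpiration is the
size-class weighted mean tree flow `Q̄ = Σ p_c·Q_c`, normalised by canopy
area (mm/day) or multiplied by stand density (trees/m²). The
representative flow per class defaults to the mean of instrumented trees
in the class; a regression mode scales flows by allometrically predicted
sapwood area at the class mid-diameter.

## Eddy covariance and reference ET

Windows are despiked by replacing points beyond 6 robust SDs
(1.4826·MAD) from the window median with linear interpolation; > 10%
replacements flags the window. Double rotation (yaw then pitch) nulls the
mean crosswind and vertical wind while preserving each sample's wind
magnitude. The scalar lag is the shift maximising |cross-covariance| with
`w` within ±max lag; a peak correlation below 3/√n (the white-noise level)
flags the scalar.

Fluxes: `H = ρa·cp·cov(w′,T′)` with moist air density from the ideal-gas
law at the measured pressure (91 kPa default) and `cp` humidity-corrected;
sonic temperature stands in for air temperature (single-unit sonic/IRGA,
no separation correction — frequency-response corrections are not
implemented and are a known small low bias). The vapour flux carries a
WPL-type adjustment, `E = (1+μσ)(cov(w′,ρv′) + (ρv/T)·cov(w′,T′))`, and
`LE = λ(T)·E` with `λ = 2.501 − 2.361e-3·T` MJ/kg (linear in temperature;
the record spans a wide range, so a constant λ was rejected). `ETa =
LE·Δt/(λ·ρw)` mm per interval; nocturnal negative LE is clamped to zero
for water-budget totals but retained signed in flux outputs.

Soil heat flux adds the storage above the 8 cm plates:
`G = G_plate + Cs·(dT/dt)·depth`, with `Cs = 1.942·f_mineral + 4.186·θ`
MJ/m³/K (de Vries mixing); without soil temperature the storage term is
omitted and flagged.

Reference ET is the FAO-56 Penman–Monteith form for clipped grass with
`Cn = 37` (hourly) or `900` (daily); negative instantaneous values are
floored at zero and daily ETo is the sum of hourly values (matching the
hourly-then-daily computation order). Net radiation for the ETo inputs is
approximated from solar irradiance as `0.65·Rs − 35 W/m²` clipped at
zero. `Kc` is the least-squares slope through the origin of daily ETa on
daily ETo (≥ 10 paired days), with an SE from the residual variance.

## Driver regression

Daily grain, exactly five predictors (solar radiation MJ/m²/day, wind
m/s, soil moisture vol-%, VPD kPa, ETo mm/day), OLS with intercept, no
selection or interactions. Outputs mirror the R `summary.lm` layout
(Estimate, Std. Error, t value, Pr(>|t|) plus R², adjusted R², F,
residual SE, df). Rank-deficient designs raise an error naming the
collinear columns (detected by incremental rank growth). VPD uses the
FAO-56 Tetens saturation curve: `VPD = es(T)·(1 − RH/100)`.

## Upscaling

`pixel volume = Fc_i·W_i·S` litres/day (1 mm over 1 m² = 1 L); regional
daily volume sums valid pixels, annual = daily × 365 (no leap handling —
this makes 3.4 mm/day ↦ exactly 1241 mm/yr). The invaded area is the
footprint of pixels with any cover (> 0), which is the convention the
regional mean depth refers to; the cover-weighted area is also reported
for transparency. Per-pixel map outputs are in L/day. A single
annual-mean `W_i` is used by default. Rasters travel as single-band ESRI
ASCII grids (nodata −9999, 15 m cells); a 0–100 percent scale is
autodetected on read.

## Economics

Tariff value = volume × US$ 0.00015/m³. Crop equivalents: area =
volume / water requirement (7,000 m³/ha/yr cotton, 15,000 m³/ha/yr
sugarcane), rounded to the nearest 10,000 ha for reporting (raw value
retained); tonnage = rounded area × yield (2.1 t/ha cotton, 37 t/ha
sugar); market value = tonnage × price (US$ 500–600/t cotton, 536/t
sugar). Net benefit defaults to `market·(1 − 1/BCR)` (BCR 1.49 cotton,
1.12 sugar); the alternative `market·(BCR − 1)` convention is selectable
and every output labels the formula used. All quantities are homogeneous
of degree one in volume before rounding. The report footnotes that
independently published tonnage/value figures for a given area need not
match this internally consistent chain.

## The synthetic campaign

The generator emulates the Afar study conditions and is the ground truth
for every recovery test; its defaults are fixed, not fitting knobs.

* **Weather**: half-hourly; solar is a clear-sky half-sine (peak
  1000 W/m²) scaled by a per-day clearness draw (lower during rains);
  temperature is 31 °C mean with 12 °C diurnal and 5 °C seasonal
  amplitude; RH is inversely coupled to the diurnal temperature
  excursion; pressure ~91 kPa. Rain occurs only in the bimodal rainy
  season (Mar–Apr, Jul–Sep) as daily Bernoulli (p = 0.35) ×
  gamma-distributed amounts scaled so a 365-day expectation equals
  560 mm. Mean RH (58%) and wind (1.3 m/s) were set so the FAO-56 ETo of
  the generated weather matches the reported ~5 mm/day. Soil moisture is
  a leaky bucket over daily rainfall.
* **Sap flow**: per-tree velocity curves (solar-shaped diurnal profile,
  monthly multipliers 1.104 dry / 0.883 rainy after normalisation —
  i.e. the observed 1.25 dry/rainy contrast) whose daily-mean velocities
  are back-calculated from the twelve instrumented trees' reported daily
  volumes, so the full chain recovers 6.8 / 5.1 / 8.5 L/day by
  construction. Emitted `v1/v2` ratios encode the *raw* velocity whose
  wound correction equals the prescribed truth, so the wound polynomial
  is exercised by every round trip. Noise is additive on the raw
  velocity (0.5 cm/h default).
* **Turbulence**: independent Gaussian `w, T, q` mixed by a Cholesky-style
  factor to the covariances obtained by *inverting* the WPL chain, so the
  analysed H and LE equal the targets in expectation; optional pitch tilt
  and scalar lag exercise the corrections. No spectral structure of real
  turbulence is emulated.
* **Energy balance**: daily ETa is prescribed as 0.77 × daily ETo with
  12% lognormal day-to-day noise, distributed over daylight half-hours
  proportional to solar; H closes `Rn − G`. Note 0.77 × ETo(≈5.0) implies
  ETa ≈ 3.85 mm/day; a mean of exactly 3.7 mm/day is not simultaneously
  consistent with Kc = 0.77 at this ETo, and the Kc mechanism is the one
  emulated.
* **Cover raster**: Bernoulli invasion mask with Beta-distributed cover
  (mean 0.21 on invaded pixels, κ = 2) at 225 m² pixels — the mean cover
  at which a 1.18 Mha footprint transpiring 3.4–3.85 mm/day at full cover
  yields ~3.1–3.5 billion m³/yr and a ~280 mm/yr mean depth.
* **Inventory**: uniform stem diameters, 50/50 habitat mix, sapwood areas
  from the linear allometry `A = −15 + 4.2·D` cm² (exact unless noise is
  requested), sapwood depths solved from the annulus geometry.

Because the generators are statistical emulators, passing tests
demonstrate that the *processing* is correct (unit conversions,
corrections, estimators, aggregation), not that real Prosopis stands
behave this way; instrument pathologies (drift, calibration error,
footprint heterogeneity, rain-on-sensor artefacts) are not represented.

## Problem sizes and determinism

The default end-to-end run simulates 365 days × 48 half-hours, 12 trees ×
2 probe depths, and a 400 × 400 raster; the acceptance script enlarges the
raster to 7242 × 7242 (≈52 M pixels = 1.18 Mha footprint) to compute the
regional totals at the mapped invasion's true extent. All randomness
derives from a single config seed via spawned substreams, so repeated runs
are byte-identical; every generator is likewise a deterministic function
of its own seed.

## Known limitations

* The driver-regression coefficients from synthetic data reflect the
  generator's simple dependence structure, not field coefficient values;
  the module's contract is the model form and table layout.
* No footprint modelling, u*-filtering, spectral corrections, or CO₂
  products on the EC side; no probe-misalignment correction beyond the
  wound table on the HRM side.
* GeoTIFF I/O is not provided; rasters use the ESRI ASCII grid text
  format.
* Annualisation uses 365 days everywhere, by design.
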
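# prosopis-water

Water use of invasive *Prosopis juliflora* (mesquite) stands in semi-arid
East Africa: a reproducible pipeline from raw field measurements to a
regional water budget and its monetary value.

`Prosopis` is an evergreen, deep-rooted invader of floodplains and
rangelands. Because it transpires year-round — and, counter-intuitively,
*more* in the dry season, when it taps groundwater — dense thickets can
consume a large share of a catchment's water balance. This package
implements the full measurement-to-valuation chain used to quantify that
loss, with a synthetic-data module that emulates every field instrument so
each stage is testable against known ground truth.

## What it computes

**Tree transpiration (heat ratio method).** A heater pulse and two
thermocouples equidistant up/downstream give the heat-pulse velocity

```
Vh = (k / x) · ln(v1 / v2) · 3600        [cm/h]
```

with thermal diffusivity `k = 2.5e-3 cm²/s` and probe spacing
`x = 0.5 cm`. A quadratic wound correction compensates for the drilled
holes, a sapwood-area-vs-stem-diameter allometry scales velocity to L/h
through concentric sapwood annuli, and daily, habitat, seasonal and
size-class-weighted stand aggregates follow (`sapflow_hrm`).

**Stand evapotranspiration (eddy covariance).** Despiking, double
coordinate rotation, scalar lag optimisation, and covariance fluxes
`H = ρa·cp·cov(w′,T′)` and `LE = λ·E` with a WPL density adjustment;
LE converts to an ET depth via `ETa = LE·Δt/(λ·ρw)`. Reference ET uses
the FAO-56 Penman–Monteith hourly form, and the crop coefficient `Kc`
is the through-origin slope of daily ETa on ETo (`flux_et`).

**Drivers.** Daily water use regressed on the five standard
micrometeorological drivers (solar radiation, wind, soil moisture, VPD,
ETo) by OLS with the familiar R-style coefficient table
(`drivers_regression`).

**Upscaling.** Pixel water use is `Fc_i · W_i · S` litres/day over a
fractional-cover raster (`Fc_i` ∈ [0,1], `W_i` the stand rate at 100%
cover in mm/day, `S = 225 m²`); regional totals, invaded footprint and
mean annual depth follow (`upscaling`).

**Valuation.** The basin water tariff (US$ 0.00015/m³) and
crop-production equivalents — the cotton or sugarcane area, tonnage,
market value and net benefit the same volume could support
(`economics`).

## Worked example

Run a full synthetic year — twelve instrumented trees across floodplain
and dryland sites, half-hourly weather and energy-balance series, and a
cover raster at the mapped invasion's 1.18 Mha scale:

```bash
prosopis-water report --out run_out --seed 1 --days 365
cat run_out/report.txt
```

With the full-scale raster (as used by the acceptance script) this prints:

```
== SAP FLOW ==
mean tree water use 6.8 L/tree/day
habitat means (L/tree/day): dryland=8.5, floodplain=5.1
seasonal means (L/tree/day): dry=7.5, rainy=6.0
stand transpiration 3.40 mm/day (1241 mm/yr)

== EVAPOTRANSPIRATION ==
ETa 3.85 mm/day, ETo 5.03 mm/day, Kc 0.76 (n=365 days)

== UPSCALING ==
sapflow: 3.074e+09 m^3/yr over 1180048 ha invaded (260 mm/yr, 47% of precipitation)
et: 3.478e+09 m^3/yr over 1180048 ha invaded (295 mm/yr, 53% of precipitation)

== ECONOMICS ==
tariff value $461,108 - $521,702 per year
```

Reading this: individual trees average 6.8 L/day, with drier sites —
where trees rely on groundwater — using more (8.5 L/day) than the
floodplain (5.1 L/day) and the dry season exceeding the rains (7.5 vs
6.0 L/day). Normalised over a 2 m² canopy the stand transpires
3.4 mm/day (≈1241 mm/yr at full cover), while the flux tower sees
3.85 mm/day of actual ET against 5.03 mm/day of reference ET, i.e. a
crop coefficient near 0.77. Summed over ~52 million raster pixels
(1.18 Mha of invasion at ~21% mean cover), the stand consumes
3.1–3.5 billion m³/yr — roughly 280 mm/yr, half the region's 560 mm
annual rainfall — worth about half a million US$/yr at the basin tariff,
or the irrigation water for ~470,000 ha of cotton or ~220,000 ha of
sugarcane.

Each stage is also independently runnable (`simulate`, `sapflow`, `et`,
`eto`, `drivers`, `upscale`, `econ`) on the documented CSV/ASCII-grid
files, so real logger exports can replace the synthetic inputs.

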
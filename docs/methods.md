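# Methods

## Scope and model chain

deltacrop chains four analyses: stage-wise climate suitability from daily
weather; soil-salinity suitability zoning from a salinity–yield regression;
per-salinity-class crop economics; and fertilizer-response / nitrogen
recovery analysis. Each stage reads and writes plain-text artifacts (CSV,
ESRI ASCII grid, JSON), so stages are independently re-runnable and the whole
chain is reproducible hash-for-hash under a fixed seed.

## Climate suitability

**Temperature.** The beta response
`F(T) = [(T−T_l)(T_h−T)^B]/[(T_o−T_l)(T_h−T_o)^B]`, `B=(T_h−T_o)/(T_o−T_l)`,
is the unique unimodal form that is 0 at both cardinal limits, 1 at the
optimum, and consistent with the printed exponent values (0.63 for stages
with cardinals 11/30/42 °C, 1.16 for 5.7/22.5/42 °C). Temperatures at or
outside the cardinal limits score 0 (the closed form already vanishes at
`T_l`; the upper branch is cut at `T ≥ T_h`). The default stage input is the
stage-mean daily temperature; a per-day-then-average variant is available
(`temperature_input="daily_mean"`), which is systematically lower because the
response is concave near the optimum.

**Water.** Stage precipitation is scored against the band
`[0.7·ET_c, 1.3·ET_c]`: 1 inside, `R/R_b` below (mild drought), `R_m/R`
above (mild waterlogging). `ET_c = K_c · ΣET_0` with stage coefficients
`K_c = 0.45 / 1.15 / 1.05` and the FAO-56 daily Penman–Monteith `ET_0`
(soil heat flux 0 at the daily step; psychrometric constant from station
pressure via elevation). Net radiation comes from sunshine duration through
the Angstrom relation with the FAO-56 defaults a=0.25, b=0.50, since no
radiation measurements are assumed. Missing humidity or wind raises rather
than defaulting silently.

**Sunshine.** `F(S) = min(S/S_o, 1)` is applied only in the
heading–flowering stage — the crop's single photoperiod-sensitive period —
with the fixed optimum `S_o = 11 h/d` by default; `sunshine_threshold=
"daylength"` switches to `0.7 ×` astronomical day length. The other stages
score 1 regardless of sunshine. Both threshold conventions are supported
because the source material for the index leaves the choice open.

**Stage calendar.** Three stages on fixed dates (no phenology simulation):
emergence–heading doy 135–196, heading–flowering 197–238 (sensitive),
flowering–maturity 239–280. Day-of-year windows are evaluated on a 365-day
calendar.

**Aggregation.** Per stage, the comprehensive index is the geometric mean
`(F_T·F_R·F_S)^{1/3}`; the season value is the stage-length-weighted
arithmetic mean of the stage indices (unweighted option available). Period
(decadal) values are plain means of yearly season values per station.

## Spatial interpolation and zoning

Point values go onto a regular lon/lat grid by inverse distance weighting,
`v(x) = Σ d_i^{-p} v_i / Σ d_i^{-p}`, default power 2 over all samples
(k-nearest option). Distances use an equirectangular local projection —
adequate below the centimeter level of induced error for a study area under
3° of extent — with a great-circle option. A probe within 1 mm of a sample
returns the sample value exactly, making the interpolant exact at data
points and bounded by the sample range everywhere (convex combination).
Topsoil (0–20 cm) salinity is the mean of the 0–10 and 10–20 cm layer values
per point — an assumption, since the layer-combination rule for multi-depth
sampling is not standardized.

Zoning inverts the fitted linear salinity–yield response at yield fractions
0.75/0.50/0.25 of the intercept (the zero-salinity maximum yield):
`x_f = a(1−f)/(−b)`. Breakpoints are *truncated* (not rounded) to two
decimals — the convention that reproduces all three published values
(2.6287→2.62, 5.2574→5.25, 7.8861→7.88). Thresholds derive from the linear
fit only: a convex quadratic fit has no monotone inverse on the relevant
range. Interval edges belong to the more-suitable class (salinity ≤ 2.62 ‰
is "suitable", 7.88 ‰ exactly is still "less suitable").

Statistical machinery: the linear fit reports the slope t-test p-value, the
quadratic fit the regression F-test, both two-sided at α = 0.05.

## Economics

Per (crop, salinity class): mean input-output ratio `100·output/input` and
mean economic output over households, unweighted by default (area-weighted
option). Combinations never planted are carried as an explicit "/" sentinel,
not dropped. Ranking is by ratio, ties broken by output then name.

## Fertilizer response and nitrogen recovery

Per cropping system, OLS on `Y = b0 + b1·X + b2·X²` (X = total N+P2O5+K2O
rate). A non-concave fit (b2 ≥ 0) warns and reports no optimum rather than
erroring — small survey samples make it plausible. Derived quantities:
control yield b0, optimal rate `−b1/(2b2)`, maximum yield `b0 − b1²/(4b2)`.
Apparent recovery efficiency `RE = 100·(U−U0)/F` uses above-ground uptake
`U = grain·c_grain + straw·c_straw`; the default grain/straw nutrient
content fractions are literature-typical cereal values exposed in
configuration, and negative RE is reported with a warning, not suppressed.
The two-year yield averaging rule (`(current + previous)/2 − control`) is
provided for surveys that record both years.

## Synthetic data: what it emulates, what it does not

The generators draw from one seeded `numpy` Generator per stream (fixed seed
⇒ byte-identical CSV output). Defaults are the study conditions:

* **Weather** — temperature as an annual sinusoid (mean 12.4 °C, half-range
  14.3 °C, peak mid-July) plus AR(1) daily anomalies (φ=0.7, σ=2 °C);
  precipitation as Bernoulli-gamma occurrence/amount with summer-concentrated
  expectation normalized to 551.6 mm/yr; sunshine as a Beta(3,2) fraction of
  astronomical day length (≈ 2630 h/yr); RH ~ N(0.66, 0.08) clipped, wind ~
  Gamma(4, 0.65). 365-day calendar, no leap days.
* **Soil salinity** — linear gradient rising toward the coast (northeast by
  default) from ~0.3 to ~11.5 ‰, plus six Gaussian patches (amplitude
  σ=1.2 ‰) and measurement noise, at three sampling depths; all four
  suitability classes are represented at the default 121 points.
* **Trials** — `yield = max(0, 5.3384 − 0.5077·salinity + N(0, 1.52))` at 58
  points, salinity ~ U(0, 8 ‰). The noise level was calibrated once by Monte
  Carlo so the expected fitted R² ≈ 0.38 while zero-truncation keeps mean
  slope bias under 5 %.
* **Surveys** — five cropping systems with published control yields
  (4.294/5.800/2.106/6.440/6.366 Mg/ha) and rates-at-maximum, plus
  experimental sweet-sorghum forage plots; yields on each system's concave
  quadratic plus noise; economics fields drawn around a configured
  (ratio, output) target table; N uptake increments embedding per-class
  recovery targets that decline with salinity. Printed per-nutrient rates
  are treated as N/P/K shares of the total (the printed components do not
  always sum to the printed totals).

Not emulated: interannual drought regimes (annual precipitation variability
is narrower than reality, so synthetic water suitability sits near the top
of the observed range — long-run mean season suitability ≈ 0.88), spatial
correlation of weather between stations, remote-sensing land-cover masks,
and laboratory conductivity-to-salinity calibration. Passing tests therefore
demonstrate the correctness of the index arithmetic, regression inversion,
interpolation and aggregation machinery — not that real-delta suitability
takes any particular value.

## Numerical choices and degenerate inputs

* Day length from the standard declination/hour-angle inversion; polar
  latitudes are rejected as out of scope.
* `ET_0` is clipped at 0; the cloudiness factor uses `min(Rs/Rso, 1)` (with
  Angstrom a=0.25 the factor cannot go negative for nonnegative sunshine).
* The water index is undefined at `ET_c = 0` and raises.
* Linear fits accept n ≥ 2 (two points saturate, R² = 1); quadratic fits
  need n ≥ 4 and ≥ 3 distinct abscissae, else a rank error.
* IDW with a single sample returns a constant field; an empty sample set
  raises.
* Classification is total on nonnegative salinities and pure (no input
  mutation); NaN (masked) cells stay NaN.

## Problem sizes

Default runs use 5 stations × 10 years of daily weather, 121 soil points ×
3 depths, 58 trial points, and 10–38 survey records per system and class on
a 0.01° grid; the full pipeline completes in a few seconds and the test
suite, including 500–1000-seed Monte Carlo recovery checks, in well under a
minute. These sizes were chosen to match the surveyed data volumes while
keeping Monte Carlo standard errors small.

## Known limitations

* Fixed calendar stages; no thermal-time phenology.
* No kriging or variogram diagnostics for the salinity surface; IDW only.
* Economics takes survey prices as given — no deflation or discounting.
* The RE computation assumes uptake columns are supplied (or derivable via
  the content coefficients); it does not model soil nutrient carryover.
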
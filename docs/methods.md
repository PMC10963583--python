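# Methods

This note documents the models implemented in `heatscape`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions that affect results.

## Synthetic meteorology

Each driver variable is the sum of a mean, a diurnal harmonic, an annual
harmonic and a stationary AR(1) noise process whose innovations are drawn
from a 4-dimensional Gaussian with a configurable cross-correlation matrix
(default: warm anomalies co-occur with dry air and clear skies).  Relative
humidity is generated on the logit scale of rh/100 and wind speed on the log
scale, then back-transformed, so the marginals respect [0, 100] % and ≥ 0 m/s
without clipping artefacts; the configured "mean" is therefore the median-ish
central value on the natural scale rather than the arithmetic mean (the
arithmetic mean of wind is ~10 % higher at the default noise level).
Downwelling shortwave is a clear-sky envelope (solar geometry × Meinel
transmittance) multiplied by a daily cloud-transmission factor: a
Beta(0.9, 0.6) variate driven through a day-to-day AR(1) Gaussian copula by
the fourth innovation stream, floored to exact zeros below 0.02 so that
overcast days exercise the zero-shortwave code paths (in particular the
infinite-adjustment-factor rule of the bias correction).

Defaults sketch a temperate oceanic climate at the default site
(42.883° S, 147.330° E, local standard time UTC+10): annual-mean air
temperature 12 °C with 5 °C annual and 3.5 °C diurnal amplitudes, humidity
~70 %, wind ~3.3 m/s, and a future change signal of +1.4 °C air temperature
(optionally month-resolved), ×0.99 humidity, ×1.0 wind, ×1.03 shortwave.
Model bias is offset + scale per variable, applied after generation; the
future member additionally receives the change signal *before* the biases,
so the truth the correction should recover is known exactly.

What the generator does **not** emulate: weather systems and fronts (noise is
AR(1), not synoptic), the covariance of cloud with hour-scale humidity,
precipitation, longwave forcing, and observational error structure.  Passing
tests therefore demonstrate correctness of the algorithms under known
structure, not skill on real reanalysis or GCM output.

Toy scenes are flat ground plus box buildings (shapely polygons) and
parabolic tree crowns (crown top at the stem descending to trunk height at
the crown edge), rasterised at 1 m with row 0 at the northern edge.

## Bias correction

Univariate correction is grouped quantile delta mapping: values are grouped
by (hour of day, ISO week of year) with weeks 53 folded into 52; empirical
quantile functions use type-7 interpolation on 100 evenly spaced τ levels,
with constant extrapolation of the edge adjustment factor beyond the training
range.  The projected value's τ comes from its own group's empirical CDF
(ties resolve to the lower edge of a plateau), preserving the model's
projected change at every quantile.  Corrections are multiplicative for all
four variables; because a ratio across 0 °C is ill-posed, air temperature is
shifted to Kelvin first (recorded in the configuration).  Non-finite
shortwave adjustment factors — zeros present in one series and not another —
are set to zero and counted (0/0 likewise); for other variables a non-finite
factor raises, since it indicates degenerate input rather than a physical
zero plateau.

MBCn then operates on (hour, day-of-year) groups (Feb 29 folded into
Feb 28, equivalently day 366 into 365, mirroring the week merge): iterate a
Haar-random orthogonal rotation (QR of a Gaussian matrix with sign-fixed
diagonal), additive QDM on every rotated coordinate within its time group
(rotated coordinates are signed), rotate back; stop when the multivariate
energy distance between corrected-historical and reference (computed on a
1024-row subsample, standardised by the reference mean/SD) improves by less
than 1e-4, with a 30-iteration cap and the best iterate retained on
non-convergence (with a warning).  The converged iterate contributes only
rank orderings: per group and variable, the univariate-QDM marginals are
reordered to its ranks, so the output marginals equal the univariate QDM
marginals exactly (a multiset identity asserted in the tests).  The default
rotation seed is fixed and recorded; daily groups are small (≈ number of
years), which is faithful to the grouping design — an optional wider window
was considered and rejected to keep the diurnal/annual cycles sharp.

All grouped quantile operations are vectorised across the full group set
(per-group quantile matrices plus shared interpolation weights), so a
multi-year hourly series corrects in seconds.

Physical bounds are enforced after correction (rh clipped to [0, 100], wind
and shortwave to ≥ 0) with clamp counts reported in the results object.

## Radiation and mean radiant temperature

Solar azimuth/zenith use the NOAA closed-form ephemeris (~0.1–0.2°).  The
clear-sky envelope is GHI = 1367 · 0.7^(AM^0.678) · cosZ with Kasten–Young
air mass; the direct/diffuse split uses the published Erbs piecewise
clearness-index relation, with exact closure DNI·cosZ + DHI = GHI.

Shadows are cast on a discrete geometry shared by the fast implementation
and the brute-force test oracle: rays step one cell size toward the sun with
nearest-cell (rounded-offset) sampling; a cell is building-shadowed if the
ray meets the DSM above the ray height and vegetation-shadowed if it passes
through a crown volume (between trunk height and crown top); step zero makes
cells inside footprints or under crowns shadowed at any sun position.
Shortwave transmission is 0 under buildings and 3 % under foliage (longwave
transmission 0 %, crown albedo 15 %, emissivity 90 %; evergreen canopies).
Shadows are evaluated at ground level; the person is a cylinder at 1.5 m
with view weights 0.06 up / 0.06 down / 4 × 0.22 lateral, shortwave
absorption 0.7 and emissivity 0.97.

Sky view factors integrate the maximum horizon angle over 36 azimuthal
search directions (crowns opaque, consistent with 0 % longwave
transmission), weighting each direction by cos² of the horizon angle — for
an infinite canyon this converges to the analytic cos(arctan(2H/W));
at 1 m cells the discrete value at an H/W = 1 canyon floor is within ~0.02
of 0.447.

Longwave: Prata clear-sky emissivity from vapour pressure, blended linearly
to blackbody with cloud fraction (estimated as the shortwave deficit
1 − SW/SW_clear during the day and persisted through the night, 0.5 before
the first daytime estimate).  Surface temperatures use a one-parameter
sunlit warming T_s = T_air + a · (received SW / clear-sky SW), a = 15 °C at
full sun (configurable, logged); wall emission uses a single-bounce
radiosity closure so an isothermal enclosure at svf = 0 radiates exactly
σT⁴ and gives T_mrt = T_air.  Lateral shortwave on each cylinder face is the
projected direct beam plus half of the mean of sky-diffuse and
ground-reflected components.  Deliberately omitted relative to full SOLWEIG:
anisotropic sky radiance, prognostic wall/ground temperature histories,
deciduous phenology, and any wind modelling.

Large scenes are processed as tiles with a buffer; the shadow and horizon
search radius is capped at the buffer length, which makes tiled and untiled
runs identical (bitwise, in float32) whenever the buffer is at least the
longest shadow cast into a tile.  Default tile/buffer are 50 m/50 m for
150 m sites; tests and the acceptance run use 24–30 m tiles with 16–20 m
buffers on 48–60 m toy scenes to keep runtimes in seconds.

## UTCI

The operational sixth-order polynomial in (T_air, va, T_mrt − T_air, vapour
pressure) is evaluated either directly (210 published coefficients,
term-by-term) or, for gridded fields with site-uniform meteorology, by
collapsing to a degree-6 polynomial in T_mrt − T_air per timestep and
applying Horner's rule — the two routes agree to rounding error and the
direct route doubles as the independent cross-check in the tests.  Inputs
are clamped to the polynomial's validity window (T_air ∈ [−50, 50] °C,
T_mrt − T_air ∈ [−30, 70] °C, wind ∈ [0.5, 17] m/s, vapour pressure
≤ 50 hPa) with clamps flagged; outside the humidity cap the raw polynomial
diverges, which is why the cap is part of the evaluation and of the
reference state (50 % relative humidity capped at 20 hPa) used in the
reference-condition checks.  Saturation vapour pressure uses the
Hardy/Wexler formulation (23.39 hPa at 20 °C).

Stress categories follow the standard UTCI assessment scale with strict
inequalities — heat above 26/32/38/46 °C, cold below 0/−13/−27/−40 °C —
so boundary values fall in the milder class; the binary rollups are
any-heat (UTCI > 26) and any-cold (UTCI < 0).  Thresholds are a
configuration table, not constants.

## Climatology

Site-wide extremes are exact per-timestamp max/min over cells.  Scope logic:
any-cell heat stress ⇔ UTCI_max > 26; site-wide heat ⇔ UTCI_min > 26 (cold
mirrored with < 0); site-wide no stress ⇔ neither any-cell heat nor
any-cell cold; any-cell no stress ⇔ neither site-wide heat nor site-wide
cold.  These complements make the no-stress shares identities of the stress
shares, and site-wide ⊆ any-cell nesting holds at every timestamp by
construction (asserted on every end-to-end run).

Change fields are member-wise (future − historic) means per
(hour, day-of-year), combined across members as mean or sample SD (n−1);
month aggregation uses calendar months.  Percentile ranks of future medians
within historic distributions use linear (type-7) interpolation, reporting
0/100 outside the historic range.  Stress-hour tables divide flagged hours
by the number of calendar years (configurable; June→May normalisation was
the alternative).  Cumulative stress seasons run 1 June–31 May; seasons
without any occurrence are excluded from first-occurrence medians and
counted.  The summary table rounds means to 1 decimal and percentages and
change factors to 2 (raw values retained); a zero historic percentage flags
the change factor as undefined rather than dividing by zero.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full chain on one-year
periods over 24–60 m toy scenes with one or two ensemble members — sizes
chosen so the whole suite completes in a few minutes while every code path
(tiling, night/day branches, zero-shortwave plateaus, leap handling) is
exercised.  The algorithms are O(cells × daylight hours × search radius) in
the radiation stage and O(n log n) in the correction stage, and the same
code paths scale to 150 m sites and multi-decade ensembles.

## Known limitations

- The radiation scheme's surface-temperature parameterisation is a
  deliberate simplification; absolute T_mrt values in strong sun depend on
  the warming parameter `a`, though shade contrasts and all closed-form
  limits do not.
- The UTCI polynomial is an approximation to the multi-node physiological
  model (RMSE ≈ 1.1 °C in its published validation); no clothing or
  metabolic variants are offered.
- The synthetic generator's wind has no urban canopy interaction and the
  cloud model has no hourly structure within a day.
- GeoTIFF output carries pixel scale and tiepoint tags only (no CRS tag);
  NetCDF output is NetCDF-3 via the scipy backend.
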
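# Methods

## The attenuation-index model

Seabed light under a canopy is approximated by Beer–Lambert extinction
through two media in series: the water column (coefficient `k_w`, m⁻¹,
over depth `z`) and the canopy itself, whose optical thickness is taken
proportional to the thallus area index `T_AI` with coefficient `k_a`
(per unit `T_AI`). An open-rock sensor at the same shore height sees only
the water term. For a sensor pair in the same body of water the log-ratio
`ln(I_o/I_c)` therefore equals `k_a·T_AI` identically — surface light,
depth, tide state and turbidity cancel. This cancellation is the method's
central property and is enforced computationally: noise-free simulated
deployments across a grid of surface-light, turbidity and tide settings
must reproduce `k_a·T_AI(t)` at every retained timestamp to ≤ 1e−10
relative error (measured ~2e−16).

Assumptions worth keeping in mind:

- `k_a` is constant in time. Fucoid pigment content rises in winter, which
  would inflate apparent winter `T_AI` if uncorrected; the package treats
  `k_a` as a single calibration parameter.
- The index is unit-free, so lux loggers and PAR sensors are equally
  usable, but `k_a` is sensor-specific. Spectral structure and the
  sensors' imperfect cosine response are not modelled.
- The index may be slightly negative in noisy data (canopy sensor
  momentarily brighter than the open mean). Negative values are retained,
  not clipped, so smoothing stays unbiased.

Conversions: `T_AI = index / k_a` (`k_a` default 0.7, a mid-range
literature value for fucoids); `T_AI = wet_weight · (1 − water_content) ·
specific_thallus_area` links the optical proxy to harvest data
(water content default 0.784). The specific thallus areas shipped in the
examples (0.0082 m²/g dry for *F. vesiculosus*, 0.0182 for *F. serratus*)
are reconstructions back-solved from published shore-mean wet weights and
T_AI values, not measured constants; treat them as defaults to be
replaced by species calibrations.

## Data conditioning

- **Grid alignment.** All sensors are re-indexed to one regular grid
  (default 30 min, must divide 24 h). Timestamps within 5 min of a grid
  point snap to it; light is never interpolated.
- **Open reference.** `I_o` is the per-timestamp mean of the open-rock
  sensors that report at that instant. Loggers fail in the field; the
  mean-of-available rule keeps the reference alive without imputation,
  and a coverage report exposes per-sensor data loss.
- **Mask windows** are half-open `[start, end)` so adjacent windows
  compose without double-masking; masking is idempotent.
- **Night/zero rule.** Records where either sensor is missing or at/below
  the light threshold (default 0 lux, i.e. strict positivity) are
  missing: darkness makes the log-ratio undefined, and a zero open
  reading with positive canopy light would make it infinite. The
  threshold can be raised for sensors with a noise floor.
- **Crepuscular trim.** The index shows a systematic dip near dawn and
  dusk, so records in the first and last tenth of daylight are removed
  (fraction configurable in [0, 0.5)). Daylight position is computed from
  solar geometry: Spencer's series for declination and the equation of
  time, dawn/dusk as the zero-elevation crossing of the sun's centre
  without refraction (a −0.833° rise/set convention is available as a
  switch; at a 10% trim the filter is insensitive to the convention).
  Clock time is corrected to true solar time with longitude and the
  equation of time — at 9.2° W clock noon is ~37 min from solar noon, and
  ignoring this would bias the daylight-fraction axis. Agreement with an
  independently coded NOAA-style solar calculator is within 5 minutes
  across a latitude × season grid.
- **Day of year** is fractional with Jan 1 00:00 = day 1.0 (noon on
  12 June is day 163.5) and continues past 365 into the second
  deployment year so the axis stays monotone.

## Trend extraction

LOESS with tricube weights over the `ceil(span·n)` nearest neighbours of
each evaluation point, local degree 1 by default (degree 2 available),
0 robustness iterations by default (bisquare iterations available). Span
is interpreted as a fraction of *present* points, since missingness
varies by sensor; the default 0.4 suits a year-long record. Smoothing is
applied to the retained half-hourly points directly (matching the dense
point clouds of a field deployment); a daily-median pre-aggregation mode
exists for speed. The implementation agrees with an independent
brute-force tricube weighted-least-squares solve to ≤ 1e−8 (measured
~1e−15) and with statsmodels' `lowess` (degree-1 path) to ~1e−10.

Trends are evaluated on a uniform daily grid for reporting; seasonal
extrema are the grid argmax/argmin with ties broken by earliest day.
Cross-sensor summaries use the sample (n−1) SD over sensors divided by
√n; SE is undefined (NaN) for a single sensor. Local-linear fits
extrapolate one-sidedly at the record boundaries, so an extremum reported
at the very first or last day of a record should be read as "beyond the
record", not as a dated seasonal turning point — in the year-long
simulations the late-winter trough lands on the end boundary this way.

## The drift check

Sensor stability is assessed by OLS of logger daily means on a reference
daily radiation series, then regressing the residuals on date: a
residual-date r² near zero indicates no sensitivity drift. The synthetic
intercomparison fixture couples logger and reference through the same
simulated sky (daily clear-sky mean × lognormal cloud factor) with small
independent measurement noise (σ = 0.05 on the log scale — daily means
average ~100 half-hourly readings over several sensors, so reading-level
scatter is strongly suppressed; site-to-station weather decorrelation is
deliberately not modelled because the check targets sensor behaviour).

A power limitation discovered with this fixture: the OLS residual under a
linear sensitivity decay is proportional to `R(t)·(d(t) − d̄)`, the
product of the seasonal reference and the centred decay, so the
residual-vs-date r² is (a) independent of the decay *magnitude* (r² is
scale-invariant) and (b) capped by the phase of the deployment window
relative to the seasonal cycle — ~0.38 deterministically for a
March-anchored year at 53° N, ~0.68 for a calendar year — and further
diluted by day-to-day cloud scatter in the reference. The diagnostic
therefore separates a decaying sensor from a stable one very cleanly
(decay r² ≈ 0.25–0.33 versus control ≈ 0.001–0.008 at 30%/yr), but the
absolute r² of a drifting sensor should not be expected to approach 1 the
way the control approaches 0.

## The simulator

What it emulates, and the defaults (all configurable):

| Component | Model | Default |
|---|---|---|
| Surface light | `peak_lux · max(0, sin(solar elevation))` × cloud | peak 100 000 lux |
| Cloud | AR(1) on the log scale, median-preserving lognormal | σ = 0.5, decorrelation 6 h |
| Tide | `max(0, mean + M2·cos + S2·cos)`, periods 12.42 h / 12.00 h | mean 0.9 m, M2 1.55 m, S2 0.95 m |
| Canopy | `T_AI(t) = mean + amp·cos(2π(doy − peak)/365.25)` | 4.5 ± 1.5, peak day 195 |
| Water | constant `k_w` | 0.4 m⁻¹ |
| Sensor noise | per-sensor multiplicative lognormal | σ = 0.5 (open and canopy) |
| Sensor | zero floor + quantization | 1 lux / 1 lux |
| Layout | open + canopy sensors, two patches each | 4 + 4, 30-min sampling, 1 year |

The tide constituents reproduce ~1.2 m neap and ~5 m spring daily ranges
(an M2+S2 beat, not a full harmonic analysis — sufficient for invariance
testing); the clamp at zero depth represents intertidal emersion, and the
water term vanishes when emersed. Noise is multiplicative and
median-preserving (`exp` of zero-mean Gaussian) so the log-ratio index
receives additive, symmetric, mean-zero noise — matching the heavy-tailed
character of wave lensing and making the index unbiased by construction,
which the Monte-Carlo tests confirm. The cloud factor multiplies both
sensor groups identically and cancels from the index; it matters only
through floor-censoring at low light.

What it does *not* emulate — and hence what passing recovery tests do not
demonstrate about field data: barnacle fouling and gradual sensor
degradation (handled instead by mask windows and the drift check),
canopy-edge effects where unshaded light reaches an under-canopy sensor,
seasonal variation in `k_a`, spatial patch structure beyond labels, the
speculative crepuscular sensitivity rolloff (the crepuscular *filter* is
always applied, but the simulator does not generate the dip), and any
weather coherence between sites.

## Problem sizes and numerics

Parameter-recovery experiments use 20 independent seeds of a full
year at 30-minute sampling (~17 500 timestamps × 8 sensors; ~7 000
retained index points per canopy sensor), recovering the generator's
peak (index 4.2, day 195) to within a fraction of a day on average.
Invariance checks use 6-day deployments across 27 condition
combinations; the Monte-Carlo unbiasedness check uses 250 single-day
replicates. LOESS local fits fall back to a weighted mean when the local
design is numerically singular (e.g. all neighbours stacked at one x);
evaluation at a point with zero daylight (polar night) yields NaN
daylight fractions and the record is treated as night. All randomness
flows from explicit seeds; identical seeds produce byte-identical CSVs.
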
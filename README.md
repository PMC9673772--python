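# canopylux

Low-cost monitoring of macroalgal canopy biomass from paired light
loggers.

Canopy-forming algae (fucoids, kelps) are hard to monitor non-destructively:
visual percentage cover saturates at 100% while multilayered canopies keep
adding biomass, and harvests damage the habitat being monitored. `canopylux`
implements an optical alternative: cheap lux loggers are placed under 100%
canopy cover (`I_c`) and on adjacent open rock (`I_o`), both at the same
shore height. Seabed light follows a Beer–Lambert approximation

```
I_c = I_s · exp(−k_w·z − k_a·T_AI)        (under canopy)
I_o = I_s · exp(−k_w·z)                   (open rock)
```

where `I_s` is surface light, `k_w` (m⁻¹) the attenuation of the water
column over depth `z`, `T_AI` the *thallus area index* (m² of frond per m²
of seabed, > 1 in multilayered canopies) and `k_a` the canopy attenuation
coefficient per unit `T_AI`. Because the sensors share the same water and
sky, the log-ratio

```
ln(I_o / I_c) = k_a · T_AI
```

cancels surface light, depth, tide and turbidity, leaving a dimensionless
biomass proxy (the "T_AI index"). With a canopy attenuation coefficient
(`k_a ≈ 0.7` for fucoids) the proxy converts to thallus area index, and via
water content and specific thallus area to biomass.

The package provides:

- **model** – the Beer–Lambert equations, the attenuation index, and
  index ↔ T_AI ↔ wet-weight conversions;
- **ingest** – long-format logger CSV reading, grid alignment, fouling
  mask windows, and the mean-of-open reference series;
- **solar** – dawn/dusk/daylength from solar geometry, the night/zero
  masking rule, and the crepuscular filter (first and last tenth of
  daylight removed);
- **trend** – a LOESS smoother (tricube weights, span as a fraction of
  present points), seasonal peak/trough extraction, cross-sensor
  summaries, and a sensor-drift regression check;
- **simulate** – a synthetic intertidal light-climate generator (diel and
  seasonal sun, M2+S2 spring–neap tide, seasonal canopy cycle, lognormal
  wave-lensing/sun-fleck noise, lux sensor floor and quantization) with
  known ground truth for parameter-recovery validation;
- **cli** – `canopylux simulate | index | trend | report`.

## Worked example

Generate a year-long synthetic deployment at the Galway study conditions
(30-minute sampling at 53.246° N, 4 open + 4 canopy sensors, canopy cycle
T_AI = 4.5 ± 1.5 peaking on day 195, lognormal noise σ = 0.5), then run the
pipeline:

```
$ canopylux simulate --out deployment --seed 42
seed 42: wrote deployment/loggers.csv, deployment/sensors.csv, deployment/truth.csv, deployment/config.yaml

$ canopylux index --loggers deployment/loggers.csv --sensors deployment/sensors.csv --out results
INFO canopylux.pipeline: sensor canopy-1: retained 7051 / 17521 (masked 0, night/zero 8703, crepuscular 1767)
...
wrote results/index.csv and results/filter_counts.json

$ canopylux trend --out results
peak index 4.228 on day 194.2; trough 2.126 on day 425.5 (4 sensors)
```

About half the half-hourly records are dark (night or below the sensor
floor) and a further tenth fall in the crepuscular trim; the ~7 000
retained points per sensor are smoothed with LOESS (span 0.4).
`results/summary.json` reports the cross-sensor seasonal extrema with
standard errors, on the index scale and (given `k_a = 0.7`) the T_AI
scale: here the smoothed peak index is 4.228 ± 0.003 (SE over 4 sensors)
on day 194.2 ± 0.6, i.e. a peak thallus area index of 6.04 — against a
generator truth of 4.2 on day 195 — and the trough T_AI of ~3.0 sits at
the record's end boundary in late winter. The noise-free identity, the
depth/surface-light invariance and recovery statistics over many seeds
are exercised by the test suite.

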
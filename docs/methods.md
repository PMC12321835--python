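# Methods

## Model structure and assumptions

strawsim advances a single state vector one day at a time. The supply side is
a light-use-efficiency (LUE) model: dry matter produced on a day is
proportional to the PAR intercepted by the canopy, with PAR taken as half the
daily solar integral and interception given by Beer–Lambert attenuation of a
horizontally homogeneous canopy, `1 − exp(−k·LAI)`. When the leaf-area input
is a camera-derived interception fraction (iLAI), that fraction multiplies
PAR directly and the extinction coefficient drops out. LUE is constant: the
model assumes ambient CO₂ (~400 ppm) and no developmental or temperature
modulation of radiation conversion. There is no respiration or senescence
term — LUE is a net conversion efficiency fitted to destructive dry-matter
data, so maintenance costs are folded into it.

The demand side describes organs, not pools. Every leaf and every fruit
cluster follows a fixed logistic "potential growth" curve in degree-days
(base 0 °C, no optimum-temperature correction): leaves in cumulative
temperature since transplanting offset by their emergence threshold (one new
cohort per 160 °C·d), clusters in cumulative temperature since their recorded
first-flower anthesis. Anthesis dates are inputs, not predictions — flower
initiation is outside the model. The *daily increments* of these curves,
weighted by empirical sink coefficients (0.24 for clusters; 0.07 scaled by
1.3 for leaves standing in for all vegetative tissue), give generative and
vegetative sink strengths GS and VS, and the day's fruit allocation fraction
is AF = GS/(GS+VS). Allocation is purely supply-driven: a cluster's share is
proportional to its potential increment, but nothing caps cumulative cluster
weight at the 25 g potential if supply is abundant. Harvest is implicit —
cumulative cluster fresh weight (dry weight / DMC) times plant density *is*
the cumulative yield; no ripening lag or removal bookkeeping is applied.

## Numerical and convention choices

- **Degree-day sums are inclusive**: CT on day *n* includes day 0 through day
  *n*; a cluster's TF likewise includes its anthesis day. Sums use raw daily
  means (no clamping at 0 °C); the input plausibility window (−5…45 °C)
  makes negative accumulation irrelevant in greenhouse practice, and growth
  increments are floored at 0 so organ state is monotone regardless.
- **Cluster weight accumulates as a running sum** of daily allocations, and
  cumulative yield is `Y = F · Pd / 1000` with F the (already cumulative)
  per-plant fruit fresh weight. These are the only readings under which
  cluster dry weight and yield are true cumulative quantities.
- **AF = 0 when GS + VS = 0** (no sinks active, e.g. before any leaf has
  emerged and before first anthesis); the day's dry matter then implicitly
  stays vegetative.
- **Leaves enter the vegetative sink only after emergence** (160·p ≤ CT);
  the logistic's small pre-emergence tail is excluded. No senescence rule is
  needed because increments of fully expanded leaves vanish naturally. A
  configurable `max_leaves` guards against absurd temperature inputs
  (default: unlimited).
- **Leaf-area interpolation** is linear between observation dates and
  constant-nearest outside the observed window. iLAI is an interception
  fraction; values above 1 are clamped with a warning.
- **LUE calibration** uses an ordinary least-squares line with a free
  intercept, reporting the slope: the stand starts from a nonzero transplant
  dry mass, so a through-origin fit would bias the slope. Degenerate
  abscissae or a non-positive slope raise an estimation error.
- **R²** is the coefficient of determination (1 − SSE/SST about the observed
  mean), which penalises bias; squared Pearson correlation is available via
  a method flag. Observed points are matched to simulated days by exact
  date — the simulation is daily, so no temporal interpolation is applied.
- **Logistics** are evaluated through the numerically stable `expit`, so the
  curves are exact at both tails; daily increments are differences of the
  same curve, which makes cumulative sums telescope exactly and renders the
  model step-size-invariant (halving the temperature step changes cumulative
  cluster growth only at floating-point level).

## Synthetic scenario generator

The generator emulates the Japanese forcing-culture season the model is
built for: transplant on September 18, 220 days through late April; daily
mean temperature as an annual sinusoid (mean 17.65 °C, amplitude 7.5 °C,
peak day-of-year 205) plus seeded Gaussian noise, clipped to the observed
forcing-culture envelope of 9.8–25.5 °C; greenhouse solar integrals as a
sinusoid peaking at the summer solstice and declining mid-winter, clipped to
1–18 MJ·m⁻²·d⁻¹. The radiation scale (mean 2.8, amplitude 1.5, noise 0.6
MJ·m⁻²·d⁻¹) is set by the seasonal dry-matter budget: ≈600 g·m⁻² of
dry matter over 220 days at LUE 2.75 g·MJ⁻¹ implies about 1 MJ·m⁻²·d⁻¹ of
intercepted PAR, hence mean inside-greenhouse solar integrals near
2.8 MJ·m⁻²·d⁻¹ (low winter insolation further attenuated by the greenhouse
envelope). Flowering defaults to first anthesis at 55 DAT and successive
inflorescences every 53 days (three in total); LAI rises logistically from
0.3 to 3.0 m²·m⁻² with midpoint 90 DAT, observed every 14 days. In iLAI mode
the LAI path is mapped through `1 − exp(−0.85·LAI)`, i.e. the camera sees
exactly the Beer–Lambert cover fraction. Every generator is deterministic
per seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: irregular inflorescence timing across plants, canopy
height and structure effects on camera-derived iLAI (upright petioles let a
top-down camera underestimate photosynthetic leaf area), day-to-day weather
autocorrelation, pruning, and measurement error in destructive harvests.
Because the synthetic season is smooth and its three clusters overlap
broadly, the simulated fruit fraction during harvest (interval AF′ ≈
0.68–0.94) sits higher than is typical of observed seasons, and cumulative
yield lands near the top of the observed range (≈3.5 kg·m⁻² for
≈470 g·m⁻² of dry matter). The default-season endpoint is pinned in the
test suite as a regression fixture, computed once by the implementation.

Canopy images are rendered as randomly placed green ellipses
(excess-green index well above background) on a substrate background; the
renderer returns the exact green-pixel fraction as ground truth. The
estimator classifies pixels by excess green (2G − R − B > 20, threshold
configurable) and returns the leaf-pixel fraction directly as iLAI — a
standard canopy-cover practice that is testable against the rendered truth.
Ground-area normalization is not applied: the fraction itself is what the
interception equation consumes.

## Problem sizes and tolerances

The test suite and acceptance script run entirely on generated data: one
220-day season (sub-second), 200-day single-cluster degree-day walks,
3-point metric fixtures, 240×240-pixel canopy renders, and 20-replicate
noisy calibration fits. Conservation of dry matter (cluster allocations
summing to AF·ΔDM/Pd) is asserted to 1e−12 relative; telescoping identities
to 1e−12 absolute; analytic hand values to 1e−9; stochastic recoveries
(LUE under noise, cover estimation) to 5 % and 2 % respectively.

## Known limitations

Constant LUE ignores CO₂ enrichment and winter low-light acclimation; the
degree-day clocks have no cardinal-temperature correction, so growth is
overestimated outside the optimal range; all inflorescences share one growth
curve and one 25 g potential; supply-driven allocation can overfill clusters
in high-radiation scenarios; and fruit quality, fruit number within a
cluster, and marketable-grade classification are not modelled.
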
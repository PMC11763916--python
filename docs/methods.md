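# Methods

## The daily RATIO

For one tower-day of 48 half-hourly records, the daily RATIO is the sum of
latent-heat flux (LE, W m⁻²) over the photosynthetic period divided by the
sum over all 48 slots. Two daytime rules are provided:

- `swinpot` (default): a slot is daytime when potential (top-of-atmosphere)
  incoming shortwave is positive, i.e. astronomical daylight. This is
  deterministic, available at every FLUXNET site (`SW_IN_POT`), and
  independent of weather.
- `swin20`: measured incoming shortwave above 20 W m⁻², a common
  radiation-based day/night partition that tracks the photosynthetically
  active period more closely under heavy cloud.

Day length is 0.5 h times the number of daytime slots, so day and night
lengths always sum to 24 h. Negative LE values (condensation, instrument
noise) are retained in the sums without clamping: they are exactly what
pushes a computed ratio outside (0, 1). The filter keeps site-days with
0 < RATIO < 1 strictly and reports the discarded fraction; days with an
undefined ratio (zero daily LE sum) count as discarded. A site-day enters
the analysis only if at least 90% of its 48 slots have non-missing LE
(`min_coverage = 0.9`); FULLSET variables are gap-filled, so on real data
this mostly guards against truncated files.

Aggregation to site-day resolution: per-period means for air temperature
(Ta-day, Ta-night, ΔT = Ta-day − Ta-night); daily means for VPD, Rn, CO2,
SWC; daily sums for precipitation; per-period sums for NEE, RECO and GPP;
LE is the plain sum of slot values in native units (no energy→depth
conversion). WUEi-GPP = GPP-day × VPD / LE-day is computed from the
aggregates and left undefined when LE-day ≤ 0. "Annual (monthly) mean daily
RATIO" is always the arithmetic mean of daily ratios within the period, not
a ratio of period sums.

## Coupling curves

The RATIO axis is divided into 200 uniform half-open bins [k/n, (k+1)/n)
(last bin closed; a value on an interior edge belongs to the right bin) and
the variable is averaged per bin. Curves are fitted to (bin centre, bin
mean) pairs weighted by bin counts — binning first, then fitting, with
empty bins skipped rather than interpolated. Two families:

- polynomial, default degree 6 (weighted least squares via
  `numpy.polynomial`); the coupling shapes of interest are unimodal with
  asymmetric shoulders, which degree 6 represents comfortably;
- random forest (500 trees, fixed `random_state`), for shapes a polynomial
  cannot follow; refits with the same seed are bit-identical.

Goodness is the count-weighted R² on training bins. `peak_location`
evaluates the fitted curve on a grid and returns the argmax — argmin for
NEE and NEE-day, whose curves dip rather than peak — flagging extremes that
sit on the domain boundary (monotone curves). Between-group discrepancy is
the per-bin |mean difference| profile on shared edges, summarised
separately below RATIO 0.7 where flux magnitudes across ecosystems are
expected to coincide.

## Mapping between places

A coupling model fitted in a source group is evaluated at the target's
observed daily RATIOs; predictions are compared with observations at
site-day resolution (an option aggregates to bin means first). Target
ratios outside the source fit domain are excluded and counted, never
extrapolated. Quality per variable and land-cover group (plus a pooled
"all" group): Pearson r with two-sided p (scipy), RMSE and n; groups with
fewer than 3 pairs or zero variance are reported absent with a reason.

## Bootstrap trend curves

Within each of 50 RATIO bins, B = 1000 bootstrap samples of 4000 site-day
records are drawn with replacement; a sample must contain at least 10
distinct sites, enforced by redrawing offending samples (up to 100 rounds,
then marked unusable). Bins whose pool itself has fewer than 10 distinct
sites are skipped. Per-bin RNG streams derive from (seed, bin index), so
results are reproducible bin by bin and invariant to input row order (rows
are canonically sorted first).

Each sample is summarised by the signed trend coefficient
r = sign(slope)·√R² of a straight-line fit against calendar year — for
simple linear regression this equals the Pearson correlation with year. By
default the sampled records are first averaged per year and the regression
runs on the (≤ 18) annual means: the significance band r_crit =
t_crit/√(t_crit² + n − 2) is then evaluated at n = number of years, giving
the familiar ±0.47 band for 18 years at α = 0.05, and the band and the
regression refer to the same sample size. A record-level variant
(`regression="records"`) regresses the 4000 raw records instead; its band
is evaluated at n = 4000 and is correspondingly tiny.

**Null calibration.** The type-I-error rate of the |r| > r_crit band is
checked by simulation with independent replicates (each replicate draws
fresh zero-trend annual means), which is Binomial(B, α) by construction.
Bootstrap resampling inside a fixed bin pool cannot be used for this
check: each sample's r concentrates around the pool's own empirical trend
coefficient, and because Pearson r is scale-invariant that conditioning
never vanishes as the pool grows — per-bin bootstrap rejection rates under
a zero-trend truth are conditional quantities, not α.

**Curve features.** The per-bin median r is lightly smoothed (3-bin moving
average with symmetrically shrinking edge windows). Zero-crossings come
from linear interpolation between adjacent bin centres; the vertex is the
apex of a quadratic fitted to the top region of the curve (bins within 0.1
of the maximum, at least five), which suppresses bin-level bootstrap noise
and preserves a parabolic apex to within a small fraction of a bin;
curvature sign changes of the smoothed curve are reported as descriptive
slope-regime breakpoints. Both estimators are exact (to well under one bin)
on linear and parabolic test curves.

## Drivers of the RATIO

Nine candidate factors — day length, LAI, ΔT, P, SWC, CO2, P/PET, VPD, WS —
predict the daily RATIO through a random forest. Importance is permutation
importance by default (comparable across predictor scales); impurity
importance is available, and is the variant under which a duplicated
predictor's importance splits while the combined rank is preserved (a
duplicated feature's permutation importance is near zero, since the forest
can lean on either copy). Importances are clipped at zero and normalised to
sum to one.

The P/PET wetness index uses annual sums; PET is Hargreaves–Samani
(0.0023 · Ra_mm · (T + 17.8) · √(Tmax − Tmin), FAO-56 extraterrestrial
radiation), with Ta-day/Ta-night standing in for the daily temperature
extremes since the aggregation does not carry true extremes. This is a
documented stand-in for the wetness-index recipe used with the original
archive; P/PET < 0.50 (with SWC < 10%) marks arid sites. Annual LAI joins
all site-days of its site-year. The LAI–RATIO relationship is summarised by
binned means with a standard-deviation envelope and a Spearman
monotone-trend statistic over bin means.

## Effect classification

The static rule table partitions (0, 1) with half-open intervals at
{0.55, 0.75, 0.90}: greening (which raises the mean RATIO) warms strongly
below 0.75 — 0.55 is where the Ta-day trend itself changes sign, recorded
in the rationale — warms weakly on the 0.75–0.90 plateau, and cools above
0.90. 0.75 belongs to the weak-warming regime and 0.90 to the cooling
regime. Browning flips every label. An optional split at 0.93 separates
weak (0.90–0.93) from strong (> 0.93) cooling; it is off by default.
`classify_from_trend_curve` instead reads the sign of the local derivative
of a fitted Ta-day trend curve at the queried RATIO (strength from
derivative terciles), flags near-vertex queries as "≈ no change", and falls
back to the static table when the curve is monotone.

## Synthetic flux network

The generator emulates the statistical structure the analysis relies on,
not land-surface physics:

- **Sites and days.** Default 30 sites spanning 38°S–70°N, 18 years
  (1997–2014). Day length and the half-hourly potential-shortwave profile
  come from standard solar geometry (Cooper declination), so high-latitude
  sites have genuine polar nights/days.
- **Latent RATIO.** Each site-day draws RATIO ~ Beta(μκ, (1−μ)κ), κ = 25,
  with site mean μ = clip(0.30 + 0.13·LAI, 0.05, 0.93) — the monotone
  LAI→RATIO link. Site LAI values spread over 0.4–5.2.
- **LE realisation.** Daytime LE is distributed proportional to potential
  shortwave and scaled so the daytime share equals the latent RATIO;
  night-time LE is uniform. An engineered fraction of days receives
  negative night-time LE (condensation), pushing the computed ratio above 1
  or below 0. The configured `target_out_of_range_fraction` (default 0.234)
  is the *total* expected out-of-range share: polar night/day days are out
  of range naturally (ratio exactly 0 or 1), so the injection probability
  is adjusted for the deterministic polar fraction implied by the site
  latitudes.
- **Couplings.** Flux/energy variables follow unimodal degree-6 polynomials
  u with u′(x) ∝ x⁴(p − x), whose single interior maximum sits exactly at
  the prescribed peak p ∈ [0.93, 0.95]; matter variables are decreasing
  linear with much larger noise. Because the default fit family is also a
  degree-6 polynomial, peak recovery is a pure noise question with no
  approximation bias. Between-site offsets are small for flux/energy
  variables — the generated world is one in which, at equal RATIO, a
  variable's magnitude is nearly ecosystem-independent — and relatively
  large for matter variables, reproducing the reported ordering of mapping
  skill (flux > energy > matter).
- **Trends.** Per-variable slopes versus year as functions of RATIO. The
  Ta-day profile crosses zero at 0.55 and peaks at 0.90 (max 0.044 °C/yr);
  CO2 rises 2.1 ppm/yr everywhere; GPP-day gains and NEE-day loses inside
  RATIO 0.75–0.95; other variables carry no trend. The profile's node
  placement was Monte-Carlo calibrated on the default network so the
  crossing and vertex are identifiable at the trend analysis' bin width
  (observed recovery errors ≤ 0.016 for the crossing and ≤ 0.008 for the
  vertex across independent seeds, against a 0.02 = one-bin tolerance).
- **Water balance.** Per site-day, P − ΔSWC − LE_water − R = 0 holds exactly
  with LE converted through a fixed latent heat of 2.45 MJ kg⁻¹, SWC
  interpreted over a 300 mm column, and net runoff R defined as the closing
  residual (it can be negative, i.e. run-on); SWC itself follows its
  prescribed RATIO coupling.
- **Determinism.** All randomness flows from `numpy.random.default_rng`
  seeded per (config seed, site), so equal seeds give byte-identical output
  files.

What the generator does *not* emulate: weather autocorrelation, seasonal
cycles in the couplings, gap patterns and QC flags, energy-balance closure
error, disturbance/land-use change, or any mechanistic feedback from state
to flux. Passing tests therefore demonstrate that the pipeline recovers the
structure it is designed to measure when that structure is present at
realistic noise levels — not that real FLUXNET data contain that structure.

## Problem sizes

The test suite exercises most modules on an 8-site × 4-year network and the
end-to-end checks on the default 30-site × 18-year network with B = 200
bootstrap samples; `scripts/acceptance.py` uses the same default network and
B, plus a 20 000-row subsample for the random-forest driver screen. These
sizes keep a full run to about a minute while leaving per-bin populations
(≈ 750 site-days per coupling bin, ≈ 3000 per trend bin) large enough for
the recovery tolerances above.

## Known limitations

- The daytime rules are radiation-based; a GPP-based "photosynthetic
  period" definition would shift day length at dawn/dusk and slightly move
  the RATIO distribution.
- Trend regressions are ordinary least squares; no autocorrelation-robust
  variants (Mann–Kendall, Sen) are provided.
- The Hargreaves PET stand-in biases the wetness index where the day/night
  temperature spread is a poor proxy for the diurnal extremes (high
  latitudes in winter).
- Mapping quality is evaluated at site-day granularity by default; pairing
  at bin-mean granularity gives systematically higher correlations.
- The effect classifier predicts sign and strength classes only, never
  °C magnitudes.
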
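# Methods

This note records the statistical model behind the synthetic ensemble,
the conventions and estimators used by each analysis stage, the design
choices made where the underlying standards are silent, and the known
limitations.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic ensemble

Each (model, scenario) member generates daily temperatures per station
as

    T(d) = base(lat, elev) + model offset + seasonal(d) + trend term + AR(1) noise

* **Station climatology** `base = 8 °C − 0.7 °C/°lat · (lat − 35°N) −
  6.5 × 10⁻³ °C/m · elevation`: a mid-latitude reference temperature
  with a meridional gradient and the standard tropospheric lapse rate.
  It is deterministic in the station coordinates, so all models share
  it and inter-model spread comes only from the bias term.
* **Model bias**: one offset per model, drawn once from N(0, 1 °C²)
  independently of the scenario, so two scenarios sharing a model and a
  master seed are identical before the scenario split.
* **Seasonal cycle**: a sinusoid of amplitude 12 °C with its trough in
  mid-January — typical of continental mid-latitude stations.
* **Warming trend**: linear in time after the split year (2015, the
  historical/scenario boundary of CMIP6-class experiments) at the
  scenario's °C-per-decade rate, separately for Tx and Tn.  The default
  moderate pathway warms at 0.31/0.30 °C per decade (Tx/Tn) and the
  high pathway at 0.51/0.49, the national winter rates the analysis is
  designed around.  The moderate pathway carries a `stabilization_year`
  of 2080 after which its trend stops: moderate-emission forcing
  plateaus late in the century, and without that plateau a trailing
  30-winter baseline can never catch up with the warming, leaving
  warm-winter frequency saturated under *both* pathways and inverting
  the exposure contrast the two-scenario comparison exists to measure.
  2080 specifically leaves the 2090s baseline about 0.2 °C behind the
  plateau — reduced-but-nonzero late-century frequency rather than
  either extreme.  The field defaults to `None` (purely linear), which
  every trend-recovery experiment uses.
* **Daily noise**: stationary AR(1) with marginal SD 3.5 °C and
  autocorrelation 0.7, the persistence scale of synoptic weather.
* **Ordering**: Tn and Tx are built as centre ∓ half the diurnal range
  (a station constant 8 °C plus small noise, clipped non-negative) and
  Tm is their midpoint, so Tn ≤ Tm ≤ Tx holds by construction; values
  are rounded to 0.01 °C, the resolution of station archives, which
  also makes CSV round trips exact (rounding is monotone, so it cannot
  break the ordering).
* **Seeds**: one master seed; per-(model, station) substreams derived
  with `numpy.random.SeedSequence` spawn keys, so any member is
  reproducible in isolation.

Population pathways are linear per region in persons per decade with
optional Gaussian anchor noise, clipped at zero.  The default baselines
(≈1.33 billion nationally, concentrated in the NC/SC/SW regions) and
the two pathways' decadal trends (≈ −26.3 and −61.4 million per decade
nationally) are the published regional figures the exposure analysis
uses.

**What the generator does not emulate**: spatial correlation of weather
between stations (station noise streams are independent, so regional
majority votes are sharper than for real, synoptically correlated
networks); real topography and coastlines beyond coarse per-region
coordinate boxes; monsoon dynamics or any circulation-driven regional
asymmetry; non-Gaussian daily tails; time-varying diurnal range.
Passing tests therefore demonstrate correctness of the *computations*
under a controlled statistical structure, not skill on real archives.

## Winter conventions

Winters are December–February labelled by the January year (DJF 1990/91
→ winter 1991); windows are 90 or 91 days.  A winter with more than 10 %
of days missing is excluded from means and classification — the usual
climatological completeness rule.  Members are simulated from the
December before their first year so the first winter is complete.

## Percentile thresholds and indices

Calendar-day thresholds (p10 of Tn, p90 of Tx) pool a 5-day window
centred on each calendar day over a 30-year base period and use the
linear-interpolation order statistic (`numpy.percentile` default), so
results are bit-reproducible.  The base period is *dynamic*: the 30
years ending at the last completed decade, refreshed each decade
(winters 2031–2040 use 2001–2030), matching the moving climatological
normal of the warm-winter standard; a fixed base is available by
option.  No in-base bootstrap correction is applied — the classical
refinement for in-base/out-of-base inhomogeneity is out of scope here
because every classified winter is out-of-base by construction.  Feb 29
gets its own threshold from its (sparser) window sample.

Spell indices sum all maximal runs of at least 6 qualifying days; runs
are truncated at the season boundary and never bridge winters; missing
days break runs.  GSL is computed on the calendar year (onset = first
≥ 6-day run of Tm > 5 °C; termination = first ≥ 6-day run of Tm < 5 °C
starting after 1 July; no onset → 0, no termination → through 31
December), since a growing season is meaningless inside one winter.

Under a stationary climate the out-of-base exceedance rate of an
empirical percentile estimated from ~150 pooled values is slightly
above its nominal level; the calibration check therefore uses a
±1.5-percentage-point band around 10 %.

## Warm-winter grading

σ uses the sample (n−1) denominator: the defining formula is a standard
deviation stated in words, and the trisection thresholds are in σ
units.  Thresholds 0.43 σ and 1.29 σ are applied strictly (">"), as is
the regional > 50 % rule.  The regional *strong* grade (> 50 % of
effective stations strong) is this package's decision — the standard
divides strong/weak regional warm winters without printing a cutoff,
and the same majority rule is the natural extension.  Effective
stations are those with a valid grade that winter; the national unit is
graded by the same rule over all effective stations and is deliberately
*not* the sum of regional results.  Baselines require all 30 window
winters; a station missing part of its window is ineffective for that
decade rather than silently re-based.

With correctly tracking baselines and Gaussian winters, station rates
converge to P(Z > 0.43) ≈ 33.4 % and P(Z > 1.29) ≈ 9.9 %; estimating Ta
and σ from 30 winters biases both upward by well under a percentage
point (the classification variable is t-distributed with 29 degrees of
freedom and variance inflated by 1/30), which the Monte-Carlo tolerance
absorbs.

## Trend statistics

Mann–Kendall S with the tie-corrected variance
`[n(n−1)(2n+5) − Σ tⱼ(tⱼ−1)(2tⱼ+5)]/18` and the ±1 continuity
correction (which maps |S| ≤ 1 to Z = 0); two-sided normal p-values;
default α = 0.05.  The slope companion is Theil–Sen (median of all
pairwise slopes) reported per decade, with OLS available for
comparison; timestamp ties are rejected.  No prewhitening variants are
offered.  The elevation–warming-rate relation is the Pearson
product-moment correlation between per-station decadal slopes and
station elevations.

## Uncertainty partition

The smooth fit is a degree-4 polynomial (the classical choice for this
decomposition; configurable), the reference offset is the 1995–2014
mean (a modern-climate normal; the defining formulation names no
period, so it is a configurable default), and the residual closes the
identity exactly.  Variances across models and scenarios use the
population (1/N) convention because the ensemble in hand is the object
of study, not a sample from a larger one (configurable via `ddof`).
`V` is read as: pool each model's residuals over scenarios and time,
take the variance, average over models — the reading most consistent
with a scalar, time-constant internal variability.  A degree-q fit of
white noise absorbs q+1 degrees of freedom, so recovered V runs a
factor (n−5)/n below an injected residual variance at n annual values.

## Model evaluation

r, RMSE, VE and RSR on pooled daily values over the overlap period
(default 1961–2010), pairwise deletion of missing pairs.  Both terms of
RSR use the 1/N convention, exactly as the metric is defined, so
RSR = RMSE / population SD of the observations.  Verdict thresholds are
left to the user.

## Exposure

Annual population interpolates linearly between decadal anchors (edge
years take the nearest anchor).  The national row uses the national
classification with national population rather than summing regions —
published national rows are not column sums of the regional rows, and
the two statistics answer different questions.  Event indicators are
unweighted (a strong warm winter counts once).  Reported percentages
round half-away-from-zero to two decimals, the convention of the
printed tables they are compared against.

## Problem sizes

The test suite and acceptance script run everything at desk scale, the
package's own choice of problem sizes: pipeline checks use 7–14
stations, 2–4 models and 80–140 years; oracle equivalence uses 1,000
fuzzed series (MK), 10⁵ random binary days (spells) and 300 series
(Sen); parameter recovery uses 3 stations × 6 models for trends, 20
models × 2 scenarios × 140 years for the variance partition, ~2,000
classifiable winters for the stationary grading rates and 500 winters
for the percentile-index calibration.

## Known limitations

* The generator's independence between stations overstates the
  sharpness of regional majority votes relative to real networks.
* Scenario structure is piecewise-linear warming; real pathways bend
  continuously, so decade-by-decade frequency paths are stylized.
* The percentile thresholds implement the moving-base reading of the
  "last 30 years"; a fixed-base variant is provided but secondary.
* GSL at high-latitude/elevation stations with no sustained warm run
  is 0 by convention, not missing.
* Exposure carries no intensity weighting and no within-region
  population redistribution over time.
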
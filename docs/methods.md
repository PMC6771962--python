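# Methods

## Scope and model

`rfduq` deconstructs a reference dose (RfD) of the form

    RfD = POD / (UF_L × UF_H)

where the point of departure (POD) is a daily TCDD intake (pg/kg/day)
anchored to a lipid-adjusted serum concentration (LASC, ppt) observed in the
Seveso cohorts, UF_L = 10 covers LOAEL-to-NOAEL extrapolation and UF_H = 3
human interindividual variability.  Every alternative reading the package
explores perturbs one of four levers: which serum concentration anchors the
POD, whether that concentration is TCDD-only or total toxic equivalency
(TEQ), whether it is read as a NOAEL (composite UF 3) or a LOAEL (composite
UF 30), and whether the uncertainty factors are fixed divisors or lognormal
random variables.

### Serum-to-intake scaling

The kinetic model that maps a serum concentration to the chronic intake
producing it is out of scope.  In its place the package uses an explicit
anchored proportionality: intakes scale linearly with serum level through a
published (serum, intake) pair — 235 ppt ↔ 0.020 ng/kg/day.  This is exact
at the anchor and a first-order approximation elsewhere; an optional
multiplicative `kinetic_adjustment` (default 1, i.e. off) allows an upward
correction for kinetic models known to underpredict intakes at low serum
concentrations by a factor of two or more.  The same intake-per-ppt ratio is
applied to TEQ-basis concentrations: TEQ adjustment is then equivalent to a
multiplicative factor total/TCDD on either scale, which is what makes the
sensitivity tree's cartesian product well defined.

### Calibration and inverse prediction

The exposure–response relation is log(TSH) = a + b·log(serum) + ε with
Gaussian ε, fit by OLS on natural logs.  The POD question is the calibration
inverse: the serum level x₀ = exp((log y₀ − a)/b) at which the line reaches
a TSH threshold y₀ (5 μU/mL screening, 10 μU/mL clinical recall).  Two
interval constructions are implemented:

* **approx_se** — the first-order (Massart-style) standard error
  SE(x̂₀) = (s/|b|)·√(1/m + 1/n + (y₀ − ȳ)²/(b²·Sxx)) with a t interval on
  the log scale, exponentiated.  The replicate term 1/m defaults to 0
  (m → ∞) because the threshold is a fixed cutoff, not a measured response;
  `m=1` reproduces the chemCal-style interval for a single observed
  response.
* **fieller** — exact inversion of the confidence band
  |y₀ − (â + b̂x)| ≤ t·s·√(1/m + 1/n + (x − x̄)²/Sxx).  The resulting set is
  a finite interval when the slope is well determined (g = t²s²/(b²Sxx) < 1),
  and otherwise the whole line or the complement of an interval; all three
  cases are reported as such, never clipped.  Because the membership
  statement is a t-pivot, the Fieller set has exact nominal coverage under
  the model, which the coverage simulation verifies empirically.

Upper bounds above a presentation cap (default 10⁷ ppt) are displayed as
"> cap" while the numeric value is retained.  Point estimates and interval
endpoints in ppt are invariant to the internal log base (tested against an
independent base-10 reimplementation).

### Group re-analysis from summaries

Where only group summaries are published (n, mean, 95% CI), standard errors
are recovered assuming a symmetric t-based CI on the reported scale:
SE = (CI width)/(2·t₀.₉₇₅,ₙ₋₁).  Dose groups are compared to control with a
Welch test by default (group variances in such data are visibly unequal);
the pooled test is available for sensitivity.  With summaries computed from
raw samples the summary-based test is identical to the raw-data test, which
the tests verify against `scipy.stats.ttest_ind`.  Per-group conclusions are
unadjusted by default; Bonferroni/Holm familywise control is available
(`adjust_comparisons`).  Classification: LOAEL = lowest significant dose,
NOAEL = highest non-significant dose strictly below it (top dose when
nothing is significant).  Non-monotone significance patterns are flagged,
not repaired.

### Induced-prior RfD distributions

Treating the POD and each UF as lognormal random variables makes
RfD = POD/∏UF lognormal too: log-locations subtract and log-variances add.
The package carries this closed form alongside Monte Carlo samples whenever
the inputs admit it; extreme tail placements (reference percentiles of
10⁻³⁰) are resolvable only analytically, and the Monte Carlo-only fallback
censors percentiles below 100/n_samples and says so.

* **UF prior** (`p95_nominal`, default): the nominal UF sits at the 95th
  percentile and the median is √nominal — the half-log convention of the
  probabilistic uncertainty-factor literature.  So UF 10 has median
  √10 ≈ 3.16 and log-SD ln(√10)/z₀.₉₅ ≈ 0.700.  `median_nominal` and
  `explicit` parameterizations are available, and every output records the
  convention used.
* **POD distribution**: lognormal with median at the inverse-prediction
  point and log-SD equal to the log-scale CI half-width divided by z₀.₉₇₅,
  using the always-bounded approx-SE interval.  A point-mass option is
  retained.
* **Sequential UFs** ("first 10, then 3") are independent draws whose logs
  add — identical to a single draw of the product distribution, which the
  tests assert.

The scenario grid takes the cartesian product {TCDD, TEQ} × {5, 10 μU/mL} ×
{NOAEL, LOAEL} — eight distributions.  Each reports its 2.5th-percentile
lower-bound RfD and the percentile at which the fixed reference
(0.7 pg/kg/day) sits.  Per-scenario seeds are spawned deterministically from
the run seed, so the summary table is bit-identical across runs.

The grid is evaluated on the **fixed-design calibration fit**: the
`CalibrationFit` whose sufficient statistics are the expected values implied
by the generator parameters (`population_fit`).  The grid models one fixed
regression, not resampling variability; a single noisy n = 51 replicate can
by accident flatten the slope enough to blur the tail placement that the
design itself implies.  Replicate-level fits are used everywhere sampling
variability is the thing under study (coverage, recovery, type-I
simulations).

## Synthetic-data generators

The generators emulate the two cohorts the analysis rests on; their defaults
are calibrated once to printed facts and are not tuning knobs.

**TSH cohort** (`TshCohortParams`): n = 51 mother–infant pairs; maternal
serum lognormal with median anchored at 18.9 ppt (the printed central level;
no dispersion is published) and log-SD solved so the expected count above
50 ppt is 5 of 51; response slope and intercept solved so the log-log curve
crosses 5 μU/mL at exactly 235 ppt and 10 μU/mL at exactly 1513.56 ppt
(slope ≈ 0.372); residual log-SD ≈ 0.510, solved so the approx-SE inverse
prediction at 10 μU/mL has a lower bound one tenth of its point estimate —
the imprecision scale of the source analysis (1513.56 vs 151.36 ppt).  The
TEQ variant multiplies every exposure by 485/235 (the published TEQ/TCDD
ratio at the POD), moving the 5 μU/mL crossing to 485 ppt TEQ without
touching the response.  A heavier-tailed exposure mixture is available for
robustness runs.

**Quartile summaries** (`QuartileSummaryParams`): a control group (n = 184,
mean 72.5, SD 36 million sperm/mL) and four exposure quartiles (n = 34 each,
SD 35) at median doses 68/135/345/733 ppt, with the depression concentrated
in the top quartile (mean 54).  The second-quartile dose is not published;
135 ppt is a synthetic geometric interpolation.  Group sizes and SDs are the
package's own realistic choices sized so that only the top quartile reaches
significance against control — the qualitative pattern of the re-analysis.
Raw draws are returned beside the summaries so summary-based tests can be
validated against raw-data tests on identical data.

What passing tests show — and don't: the generators produce exactly the
distributional shapes the methods assume (lognormal exposure, lognormal TSH
noise, normal group data).  Results on them validate the machinery, not the
biology; real cohort data carry covariates (delivery mode, sampling time,
iodine status), measurement error in exposure, and possible non-lognormal
tails that these generators deliberately do not model.

## Numerical choices

* Presentation rounding of RfDs: one significant figure (0.6667 → 0.7,
  6.667 → 7); exact values are always carried alongside.
* Fold-change rounding is caller-specified (one significant figure vs
  nearest integer), because published fold statements mix conventions.
* TEQ breakdowns accept an authoritative supplied total that overrides
  component additivity (modeled totals need not sum); a discrepancy above
  1% of the total logs a warning but stands.
* Degenerate UF nominals of 1 get a log-SD floor of 10⁻⁹ (numerically a
  point mass).
* Seeds are mandatory for all Monte Carlo; per-scenario seeds derive from
  `numpy.random.SeedSequence` spawning.
* Simulation sizes in the test suite: 2 000 replicate cohorts (n = 49) for
  interval coverage, 10 000 replicates for the type-I rate, 10⁶ draws for
  Monte Carlo/closed-form agreement, 200 replicates for the discrete
  classification rates.  These sizes put Monte Carlo error comfortably
  inside the asserted bands.

## Known limitations

* The serum-to-intake map is a one-point proportionality; away from the
  anchor it ignores the nonlinear kinetics of TCDD accumulation and
  elimination.
* TEQ handling is aggregate TCDD vs non-TCDD; no congener-level TEF
  arithmetic.
* Only the crude (unadjusted) exposure–response regression is implemented;
  a covariate-adjusted slope can be supplied externally as a
  `CalibrationFit` but not estimated here.
* The induced prior is exactly that — no posterior updating with data.
* The printed lower-bound range (~1.5–179 pg/kg/day) and reference
  percentiles (0.5 down to 10⁻³⁰) of the source analysis depend on a UF/POD
  parameterization that is not published in the main text; under this
  package's default conventions the corresponding quantities are computed
  and reported, but numerical equality with those figures is not asserted
  anywhere.
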
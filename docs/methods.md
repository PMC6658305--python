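# Methods

## Episode definition and extraction

Times are real-valued hours relative to the anchoring vaccination
(vaccination instant = 0). Readings at time ∈ (0, 48] h enter the analysis;
the half-open lower bound excludes a reading logged at the vaccination
instant itself. Readings sharing a timestamp are collapsed to their maximum
(a conservative choice for a fever analysis; the collapse is logged).

Fever is T ≥ 38.0 °C. We use ≥ rather than > so that a reading of exactly
38.0 °C counts as febrile, which matches how caregivers treat the threshold
(dosing concentrates *at* 38.0 °C, not just above it). Between readings the
temperature is imputed linearly; onset and offset are found by exact linear
inversion of the bracketing segment, not by grid search — a dense-grid
scanner exists only as an independent test oracle. With multiple threshold
crossings, onset is the *first* upward crossing and offset the *last*
downward crossing, so an episode spans sub-threshold dips. If the first
in-window reading is already febrile, onset is that reading's time and the
episode is flagged `onset_censored`. If the final reading is febrile the
offset is unobserved and the record yields no episode (and fails the
cascade's onset/offset stage). Tmax is taken from raw readings only:
linear imputation can fill gaps but cannot manufacture an extremum, so
reading it off the interpolant would never change the answer and would
obscure provenance.

The filtering cascade is: demographics present → single vaccination per
child-day (a combination vaccine given as one shot, e.g. DTaP or MMR, is a
single vaccination) → ≥ `min_readings` (default 5) in-window readings →
episode with both onset and offset → ≥ `min_records_per_vaccine` (default
100) surviving records for the vaccine. Stage counts are reported and are
monotonically non-increasing by construction. The antipyretic group is any
record with ≥ 1 dose at time ∈ [0, 48] h (a dose at the vaccination instant
is prophylactic and counts).

## Antipyretic patterns

First-dose timing is binned hourly over [0, 48). The temperature at a dose
is the imputed curve at the dose time; a dose outside its record's reading
span falls back to the nearest reading within 1 h, else it is counted as
unlocatable and excluded from the temperature distribution only.
Temperatures are binned at 0.1 °C with round-half-away-from-zero, the
granularity at which the 37.9 vs 38.0 °C dosing discontinuity is visible.
By default only first doses enter these analyses (`all_doses=True` is
available).

## Statistical battery

- **Welch t test** with Satterthwaite degrees of freedom; two-sided p from
  the t distribution. Both-samples-constant-and-equal is reported as
  t = 0, p = 1 with a degenerate flag.
- **One-way ANOVA** (classic F) plus **Levene's test** with absolute
  deviations from group means. The F test is reported even when Levene
  rejects; the post hoc procedure is what adapts to heteroscedasticity.
- **Dunnett T3**: for each pair, the Welch-type standardized mean
  difference with its Satterthwaite df, referred to the studentized maximum
  modulus (SMM) distribution with m = k(k−1)/2 comparisons. The SMM
  survival function is evaluated by 400-node Gauss–Legendre quadrature on
  the probability transform of the chi-square scale; a seeded Monte Carlo
  evaluator (10⁶ draws) is provided as an independent cross-check and the
  two agree to ~10⁻³ in p. Quadrature is the default because it is
  deterministic, faster, and at least as accurate. Adjusted p values are
  clamped from below by the pair's unadjusted Welch p, enforcing the
  multiplicity bound exactly. The homogeneity partition is the union-find
  closure of non-significant pairs, ordered by group mean.
- **Logistic regression** of high fever (Tmax ≥ 39.0 °C) on age (months),
  weight (kg) and sex (female = 0 reference, male = 1 — the coding is a
  package choice and is configurable), fitted by Newton-type iteratively
  reweighted least squares (statsmodels backend; tolerance 10⁻⁸, ≤ 100
  iterations) with Wald standard errors. Confidence intervals use the
  normal quantile 1.959964: OR = exp(B), CI = exp(B ± 1.96·SE). Perfect
  separation raises an error naming the separating predictor where one
  predictor alone is responsible. Models are fitted on extracted episodes
  (records surviving the whole cascade), per vaccine and pooled.
- **VIF** per predictor via auxiliary least-squares regressions,
  VIF = 1/(1−R²), flagged at ≥ 10; exact collinearity is reported as an
  infinite sentinel. With exactly two predictors the two VIFs are equal
  (shared R²).

No multiple-testing correction is applied across the per-vaccine Welch
tests; the battery reports each test at its nominal level.

## Trajectories

Readings of records with an episode are mapped to relative time =
reading time − onset and pooled into 1 h bins with integer centers on
[−3, +24]; each bin reports the mean and a t-based 95% CI half-width
(0 when n ≤ 1). An alternative statistic (`per_record_means=True`)
contributes each record's imputed value at the bin centers its reading span
covers, with no extrapolation. The decay fit is ordinary least squares
through non-empty post-onset bin *means* (default window 0–24 h);
R² = 1 − SSE/SST, with SST = 0 reported as a degenerate R² = 0.

## Synthetic cohort generator

The generator emulates the statistical structure of caregiver-logged
postvaccination data, with every child vaccinated at t = 0 and observed
48 h:

- **Latent fever**: baseline ~ N(36.9, 0.15) °C; with vaccine-specific
  probability (0.75 for the five major vaccines) a triangular pulse —
  linear rise over 4–5 h to an individual peak, then linear decay at an
  individual rate. The pulse is anchored so the latent curve crosses
  38.0 °C upward at the drawn onset latency. Decay rates are lognormal
  around the vaccine's typical rate (log-sd 0.7), producing the very wide
  spread of fever durations caregiver data show.
- **Vaccine tiers**: default kinetics place hepatitis A and influenza in a
  high tier (peak 39.0 ± 0.4 °C, decay 0.055 °C/h, onset latency 12–13 h),
  Japanese encephalitis and DTaP in a middle tier (38.7 °C, 0.07 °C/h,
  10–11 h) and pneumococcus in a low tier (38.4 °C, 0.11 °C/h, 9 h), with
  identical parameters within a tier — the tiers, not within-tier ranks,
  are the meaningful structure. Seven minor vaccines share a mild profile
  and appear rarely, so the per-vaccine minimum-records rule has work to
  do. Per-vaccine fever incidence is an assumption of the generator, not
  an estimate; no public per-vaccine incidence suitable for calibration
  exists at this granularity.
- **Antipyretic effect**: each dose subtracts
  `magnitude · max(0, 1 − Δt/4.4 h)` from the latent curve, floored at
  baseline — a linearly waning suppression (default magnitude 1.0 °C) with
  full rebound to the latent fever course, the simplest shape consistent
  with a transient ~4.4 h effect.
- **Caregiver behaviour**: measurement is an inhomogeneous Poisson process
  (0.15/h afebrile, 0.8/h febrile — caregivers measure more when the child
  is hot); readings add N(0, 0.1) °C noise, clipped to [34, 43] °C. At each
  reading a dose follows with probability 0.6 if the measured value is
  ≥ 38.0 °C, scaled by 0.1 below the threshold, never within 6 h of the
  previous dose. Two per-child traits add realism: 15% of caregivers give a
  temperature-independent prophylactic dose within the first hour, and 3%
  never medicate. Measurements and doses are simulated jointly forward in
  time, since doses change both the temperature later readings observe and
  the measurement intensity.
- **Demographics**: age ~ Gamma(1.6, 9.6) months (median ~1 y, mean ~15 mo);
  weight = 0.4·age + 4 + N(0, 1) kg, making age and weight strongly
  collinear (VIF ≈ 20–25 — the age spread of a routine-immunisation cohort
  combined with a tight growth relation puts the pair well above the
  VIF = 10 screen, which the reports duly flag); sex is 60% male. 3% of
  records lack demographics and 5% of children receive a second same-day
  shot, so the cascade's early stages are exercised.

Defaults were chosen once to reproduce the qualitative phenomenology of
app-logged postvaccination fever: onset latencies ~9–15 h, peaks
38.3–39.0 °C, sub-threshold return typically < 24 h after onset, dosing
concentrated at ≥ 38.0 °C (~85–90% of first doses), a first-dose spike
within the first hour, most first doses within 10 h, and a flatter
post-onset decline in the medicated group. The generator reproduces these
*patterns*; it is not calibrated to any real cohort, and its defaults are
qualitative emulation only.

What the generator does **not** emulate: repeat vaccinations of the same
child across days, multi-shot visit structure beyond simple same-day pairs,
diurnal temperature rhythm, measurement-site or device effects, dose
magnitude (carried but unused), or informative drop-out beyond the
temperature-coupled measurement rate. Passing tests therefore demonstrate
correctness of the pipeline under a known data-generating process with
realistic irregular sampling — not fidelity to any particular real-world
cohort.

Ground truth records the *untreated* latent pulse's onset/offset/duration
and peak. Recovery checks consequently disable dosing; with noiseless dense
sampling the extracted means match ground truth to ≲ 0.05 h (interpolation
across the pulse-start kink and apex is the only bias source), and within
1 h with default noise.

## Numerical and design notes

- Crossing inversion is exact for piecewise-linear data; the dense-grid
  oracle used in tests evaluates the interpolant every 0.001 h *and* at the
  reading instants, because a curve can touch 38.0 °C exactly at a reading
  (a measure-zero event a regular grid misses).
- Duplicate-time readings: maximum kept, count logged.
- Degenerate inputs are values, not crashes: no-fever records yield no
  episode; constant groups yield flagged degenerate test results; SST = 0
  yields a flagged R² = 0.
- Problem sizes in the validation suite (2,000-child shared cohort;
  500 children for recovery; 100 seeds × ~400 episodes/group for the post
  hoc partition; 50 seeds × 3,000 children for the decay contrast; 10,000
  null replicates for Welch calibration) are the package's choices for
  stable Monte Carlo verdicts at desk scale.
- Determinism: every stochastic component takes a seed or `Generator`;
  `run_pipeline` writes byte-identical reports for identical seed, config
  and inputs, and the manifest records input digests so tampering is
  detectable.

## Known limitations

- Onset censoring (first reading already febrile) biases onset late in
  sparse records; the flag is carried so users can sensitivity-check.
- The T3 SMM reference treats the m pairwise statistics as independent
  given the scale, as the classical procedure does; it is conservative for
  the positively correlated pairs that share a group.
- The high-fever logistic model conditions on an extracted episode, so its
  estimates concern children whose fever was observed to resolve within
  the window — the same conditioning the cascade imposes on every
  downstream analysis.
- Real caregiver data have duplicated children across vaccination records;
  records are treated as independent, and no mixed-effects structure is
  fitted.
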
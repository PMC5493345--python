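# Methods

## Model

A cohort at equilibrium (constant recruitment, constant total mortality)
has age density proportional to e^(−Z·a). A catch sample additionally
reflects selectivity s(a), so the sampled-age density is

    f(a) ∝ s(a) · e^(−Z·a),            Z = M + F  (1/yr),

with M natural and F fishing mortality. Above the age of full recruitment
(s ≈ 1), the logarithm of the age-frequency declines linearly with slope
−Z: the catch curve. The package estimates Z per group and attributes
between-group differences in Z to differences in F, using the no-take area
as the F = 0 reference (M is assumed spatially constant; the no-take
estimate of Z proxies M everywhere).

Lengths, not ages, are observed. Ages are assigned deterministically
through the inverse von Bertalanffy curve a(L) = t0 − ln(1 − L/L∞)/K. The
forward/inverse pair uses `expm1`/`log1p`; even so, the inverse is
ill-conditioned near the asymptote (1 − L/L∞ cancels), which is a real
feature of length-converted catch curves, not a numerical nuisance — see
*Known biases* below.

## Estimation pipeline

Per group (species × regime, site, management area or year):

1. **Ageing.** Records with L ≥ L∞ have no finite age; by default they are
   dropped, counted and logged (`over_linf="clamp"` instead assigns the age
   at 0.999·L∞). Dropping is conservative and auditable.
2. **Binning.** Ages go into half-open 0.2-yr classes [i·w, (i+1)·w) on a
   grid anchored at age zero; a boundary age belongs to the upper class.
   0.2 yr is narrow enough not to mask the onset of the descending limb.
3. **Right-tail truncation.** Scanning right of the modal class, everything
   from the first run of ≥ 4 consecutive zero-count classes onward is
   discarded. Gaps left of the mode (under a sparse ascending limb) never
   trigger truncation — a left-to-right scan would otherwise discard the
   whole curve when a single very young animal appears.
4. **Age of full recruitment.** A cubic smoothing spline is fitted to the
   raw class counts against class midpoints — smoothing parameter chosen by
   generalized cross-validation, overridable (`spline_lam`), with an option
   to fit on log counts (`spline_on_log`) — and evaluated on a grid of step
   w/20; the maximizer is the recruitment age. With exactly 4 classes (the
   minimum) an interpolating cubic replaces the smoother, which needs 5
   points. The limb starts at the class *containing* the recruitment age
   (the peak class is included).
5. **Regression.** Unweighted OLS of ln C on A over the limb's
   positive-count classes (zero counts are skipped — their log is
   undefined — rather than offset by +1, which would introduce a bias
   constant). Ẑ = −slope, reported as a positive magnitude with its
   standard error, t-based 95% CI and R²; at least 3 usable classes are
   required.

**Slope comparisons.** Groups are compared by stacking their limb
observations and fitting ln C ~ group × age. The group:age interaction F
(Type II sums of squares — symmetric under the unbalanced group sizes this
design produces) tests slope homogeneity. Because the model is saturated in
group × age, its per-group slopes equal separate per-group OLS fits exactly;
both are reported. Pairwise post-hoc comparisons are single-df contrasts on
the slope difference within the same model (F = t²), unadjusted by default
with Holm's correction behind a flag, matching how such post-hoc values are
customarily reported raw. Regime-within-site comparisons use the same
machinery on (site, regime) cells after pooling each site's management
areas and open-access grounds, so the interaction has (cells − 1) numerator
df. With perfectly collinear (noiseless) groups both the interaction and
residual sums of squares are machine zero; the implementation resolves the
0/0 explicitly (F = 0 when slopes agree, +inf when they differ) instead of
reporting floating-point noise.

**Temporal analysis.** Annual MA-level Ẑ values are regressed on year as a
continuous single-df predictor, giving an F test on (1, n − 2) df — with the
54 loco and 53 limpet management-area × year cells of the study design this
yields residual df 52 and 51. The two species' MA × year Ẑ series are
compared with a pooled-variance Student t-test, df = n1 + n2 − 2 = 105.
(Year as a 15-level factor would be incompatible with a single-df test; the
per-MA across-year ANCOVA keeps year as a factor on the age-frequency data.)

**Frequency-matched subsampling.** To stop one open-access site from
dominating a pooled regional curve, larger sites are downsampled to the
smallest admissible site's n while preserving their own class proportions:
quotas are proportional allocations rounded by largest remainder (so they
sum exactly to the target; ties broken toward larger classes then lower
bins), then drawn without replacement within class, seeded. Strata below
the minimum reliable sample size (200, from the bootstrap criterion below)
are excluded and reported.

**Minimum sample size.** For candidate sizes n (default 25, 50, … ), the
mean Kolmogorov–Smirnov distance between subsample and full empirical
length distributions over seeded without-replacement draws is compared to a
criterion (default 0.05, 500 replicates); the smallest passing n is
reported, or a "not attained" sentinel with the full distance profile. The
reliability criterion itself is an explicit package choice — operational
definitions of "reliable size-frequency distribution" vary, so every knob
is exposed.

**Decomposition.** F̂ = Ẑ − M̂_ref exactly; negative values (sampling noise
or reference error) are flagged, never clamped. Percent differences vs the
reference are rounded half-away-from-zero to integers. For a species whose
extraction is banned in open access areas (the loco), F̂ > 0 there is
reported as inferred illegal fishing.

## Synthetic survey generator

No raw survey data are public, so all testing runs on simulated records
with exactly the structure the estimator assumes:

* ages sampled by inverse CDF from f(a) ∝ s(a)·e^(−Z·a) on (0, max_age],
  with logistic selectivity s(a) = 1/(1 + e^(−λ(a − a_r))) (knife-edge in
  the λ → ∞ limit);
* lengths = von Bertalanffy mean at age × (1 + ε), ε ~ N(0, cv²) truncated
  at −1, continuous (no measurement rounding); lengths above L∞ occur and
  exercise the drop policy;
* per-cell seeds spawned from a master seed, so fixtures are reproducible
  bit-for-bit and editing one cell never perturbs another's draws.

Defaults (per species; all overridable):

| parameter | loco | keyhole limpets | rationale |
|---|---|---|---|
| L∞ (mm) | 150 | 110 | documented placeholders at the scale of the largest measured animals; the growth literature's K values do not pin them down, so configuration must supply them for real data |
| K (1/yr) | 0.433 | 0.160 | the study taxa's reported growth coefficients |
| t0 (yr) | 0 | 0 | placeholder |
| recruitment age a_r (yr) | 2.5 | 5.0 | age at each fishery's minimum exploited size (~100 mm loco, ~60 mm limpets) |
| selectivity slope λ (1/yr) | 8 | 4 | a length-based knife edge blurred by length variability at a_r maps to roughly this age-scale steepness; gives the spline rule an ascending limb a few classes wide |
| length CV | 0.05 | 0.05 | low end of typical individual length-at-age variability in gastropod growth studies |
| max age (yr) | 12 | 25 | plausible longevity |

The fixture generator mirrors the study design table (regimes × sites ×
management areas × years, published per-cell sample sizes, one limpet cell
missing) with generating mortalities anchored to the published regional
estimates: loco M = 0.98, Z = 1.39 (MA) and 1.88 (OAA); limpets M = 0.48,
Z = 0.49 (MA) and 0.78 (OAA); F = 0 in the no-take area.

What the generator does **not** emulate: spatial heterogeneity in M or
recruitment, year effects (historical cells share their regime's constant
mortality), measurement rounding, size-selective diver behaviour beyond the
logistic, bimodal size structures. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to their violation in field data.

## Known biases of the regression catch curve

Characterizing the estimator on simulated cohorts shows a systematic
*downward* bias of Ẑ at realistic sample sizes, with three causes:

1. **Sparse-tail flattening.** Classes keep entering the regression while
   their expected count λ < 1, where E[ln C | C ≥ 1] ≈ 0 regardless of λ;
   since zero-count classes are skipped, the observed tail flattens. These
   are the highest-leverage points of the fit, and the 4-zero-gap rule
   truncates only after they have accumulated. At Z = 1, n = 2000 the
   effect alone is ≈ −8%; it grows with n (a larger sample lights up more
   sub-unit-λ classes), so heavily pooled groups are biased more than small
   ones.
2. **Selectivity contamination at the limb start.** The spline maximum of
   s(a)·e^(−Z·a) sits where s = 1 − Z/λ, so the first limb classes are not
   fully selected and the limb starts concave; the effect grows with Z/λ.
3. **Ageing noise near the asymptote.** Multiplicative length error maps to
   age error with variance increasing in age (σ_age ≈ cv·L/(K(L∞ − L))),
   smearing old animals into a long thin tail of 1–2-count classes and
   flattening the slope further (locally ∝ Z²σσ′).

Together these put Ẑ roughly 10–30% below Z for Z ≥ 1 under the default
generator, and nominal 95% CIs — whose widths reflect only class-level
scatter — undercover accordingly. Count-weighted WLS shrinks the variance
but concentrates weight in the selectivity-contaminated region and does not
repair coverage, so the conventional unweighted form is kept. The
consequence for interpretation is the one the pipeline is built around:
absolute mortality levels are conservative, while *contrasts* between
groups estimated at comparable sample sizes remain directionally reliable —
the regional ordering NT < MA < OAA is recovered in ≈ 90% or more of
synthetic surveys at 2000 records per cell, and the open-access excess over
the no-take reference is always strongly positive when the generating F is.
Users comparing groups with very different pooled sizes should expect the
larger pool's Ẑ to be pulled down harder (see point 1).

## Numerical and test choices

* Degenerate inputs are decided explicitly: perfect-fit ANCOVAs (above),
  zero-variance t-tests (error), all-over-asymptote samples (error),
  sub-minimum limbs (error naming the group).
* The growth round-trip is validated to 1e-9 for lengths below 0.999·L∞;
  closer to the asymptote float64 cannot support that tolerance.
* Test problem sizes: the statistical suites run at 2000 records per
  cohort (200 replicates for recovery, 50 seeded surveys end-to-end, 500
  replicates for null calibration of the interaction test with Gaussian
  class noise, where the F test's size is exact); the multi-year design is
  exercised at 600 records per cell, enough for every one of the 107
  management-area × year cells to support a fit, which is what makes the
  design's degrees of freedom (105; 52/51) reproducible.
* The acceptance script reports the comparative survey at the published
  per-cell sample sizes, and the temporal analysis at 600 records per cell
  for the same reason.

## Limitations

Chapman–Robson and Poisson-GLM estimators, which largely avoid bias source
(1), are deliberately out of scope, as are Gompertz/seasonal growth,
mixed-effects or permutation ANCOVAs, and any extrapolation from mortality
differentials to illegal catch tonnage. The no-take reference carries the
usual caveat that residual poaching would inflate M̂ and deflate inferred F
everywhere else.
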
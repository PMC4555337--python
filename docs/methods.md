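# Methods

## The simulated population

The generator produces a closed birth cohort of `n` children. Two
standard-normal exposures are drawn jointly with correlation `rho`
(default 0.7); only the first is causal, the second exists to be a
realistic non-causal co-exposure in the regression models. Sex is
Bernoulli(`male_prob` = 0.5). True gestational age is `43 − γ` weeks
with `γ ~ χ²(3)` (mean 40, left-skewed, as in a live-birth population),
and a random `male_shift_frac` = 5% of boys lose one further week,
reflecting the shorter average gestation of males. Observed gestational
age adds a reporting error `ε_ga ~ N(0, sigma2_ga)` before rounding to
whole weeks; children outside 23–43 completed weeks are excluded and
redrawn until exactly `n` remain, so every cohort has identical size.

`sigma2_ga` defaults to (1/7)² — a one-day reporting error — and is
configurable; nothing downstream is sensitive to it because gestational
age enters the models only through the 37-week dichotomy.

Both exposures are observed under classical additive error,
`W = X + ε`, `ε ~ N(0, σ²)`, with every error stream independent of
every other draw. The causal-exposure variance `sigma2_w1` is the main
experimental axis: {0, 0.0625, 0.25, 1}, i.e. from error-free through
6%-of-signal to error as large as the signal.

### Random-number organization

One master seed spawns named independent substreams (covariates, sex,
male shift, each measurement-error source, outcome noise) via
`numpy.random.SeedSequence.spawn`. Exposure errors are stored as
standard-normal quantiles and scaled by `sqrt(σ²)` at assembly. Two
consequences, both deliberate:

* changing one variance never perturbs any other variable's draws;
* cohorts at different error levels are *paired* — same children, same
  error quantiles — which removes between-cohort Monte Carlo noise from
  every "increasing error" comparison and sharpens the monotonicity
  checks. One base draw therefore serves the whole 36-scenario grid.

## Latent outcome and case definition

The latent outcome adds `β₂X₂ + β₃Z + β₄X_ga + ε_y` (with `β₂ = 0`,
`β₃ = 1`, `β₄ = 0.1`, `ε_y ~ N(0,1)`) to a causal term that is piecewise
in X₁ around the inflection point `mean(X₁) − SD(X₁)`, computed from the
realized cohort rather than fixed at −1: slope multipliers (0, 1.5) for
the threshold shape and (1.5, 0.5) for saturation, applied to `β₁X₁`
itself. Because the multipliers scale `β₁X₁` and not `β₁(X₁ − c)`, the
latent outcome jumps at the inflection point; the formulas are
implemented exactly as specified, discontinuity included, since the
discontinuity is part of the scenario definition, and the boundary
point belongs to the upper branch.

The severity score maps Y monotonically onto the 0–18 integer scale of
an infant autism observation instrument: Y is standardized, passed
through `exp(mu_log + sigma_log · y_std)` (defaults `mu_log = 1.3`,
`sigma_log = 0.6`), rounded, and clamped into [0, 18]. This is a
synthetic stand-in with a lognormal severity profile, not a calibration
to any real instrument's distribution; the defaults were chosen so that
the case definition (score ≥ 7) yields a prevalence in the 15–20% range
plausible for an enriched-risk cohort, and they are config-exposed.
Clamping (not exclusion) is used at the score boundaries so the cohort
size stays fixed; exclusion is reserved for the gestational-age
criterion where it mimics the live-birth inclusion rule. Absolute OR
magnitudes depend on this transform, which is why the package's
acceptance surface is the *qualitative geometry* of the OR curves
(shapes, orderings, crossings) rather than reproduction of any specific
OR value.

## Rounding

Gestational age uses round-half-away-from-zero (`R(x) =
sign(x)·floor(|x|+0.5)`), not banker's rounding; a `floor` mode
("completed weeks" in the obstetric sense) is available via
`ga_round_mode`. The severity score uses the same tie rule. The
half-away rule matters only on the half-integer grid and is pinned by
an exhaustive unit test.

## Categorization

The dichotomization grid is built from integer indices (`lo + k·step`)
to avoid cumulative floating-point drift; the default −3…+3 by 0.1
yields exactly 61 cutoffs, symmetric about 0. Grid values are in SD
units and are resolved against the empirical mean and SD of the variable
actually being dichotomized, so "mean + k SD" tracks the error-inflated
spread of W₁ (SD √(1+σ²)) rather than assuming unit variance; a raw
scale mode exists for absolute cutoffs. The exposed side is closed
(`W ≥ φ`), matching the convention used for all dichotomized covariates
(W₂ at 1, gestational age at 37 weeks).

The five-category scheme places four cutoffs at
`center + SD·δ·(−1.5, −0.5, +0.5, +1.5)`: three interior groups of equal
width δ·SD with the reference (category 3) centered on the mean, and
unbounded tail groups 1 and 5. Intervals are half-open on the right.
The default δ sweep is 0.5–1.5 SD in steps of 0.1; any vector of widths
(e.g. a fine 0.01 sweep) can be passed instead.

## Estimation

Every model is the logistic regression
`logit P(case) = c₀ + c₁W₁c + c₂W₂c + c₃Z + c₄W_gac` with all predictors
dichotomous (or the 5-level exposure dummy-coded against category 3).
Fits use iteratively reweighted least squares on the covariate-pattern
count table with frequency weights (statsmodels GLM/Binomial), which is
algebraically the row-level likelihood; the equivalence is asserted to
6 decimals in the tests. 95% intervals are Wald on the log-odds scale —
plumbing for the plots and monotonicity checks, not a study output.
No multiple-testing adjustment is applied anywhere: the object of
interest is the whole curve, not any single test.

Degenerate fits are recorded, never raised: a cutoff that empties a
cell of the exposure × outcome margin gets `separation = True` and a
missing OR (shown as a gap in the curves), and adjustment covariates
that are constant in a stratum are dropped silently. Undefined
sensitivity/specificity ratios (0/0 at extreme cutoffs) are reported as
missing rather than 0 or 1, keeping the instability of the extremes
visible instead of painting over it.

The error-free reference curve (X₁ dichotomized) is computed once per
(shape, effect size) and shared across error levels — it does not
depend on σ², and with σ² = 0 the W₁ curve coincides with it exactly
(asserted pointwise in the tests).

## ROC construction

Truth is fixed by dichotomizing the error-free exposure at one named
cutoff; the mismeasured exposure is then swept as a continuous
classifier over the same 61-point grid, each threshold contributing
(1 − specificity, sensitivity). The polyline is closed at (0,0) and
(1,1) and summarized by its trapezoidal area. This is the one reading
under which "one ROC curve per selected cutoff" is well defined.

## Problem sizes and tolerances

The full study runs at n = 10⁶. The packaged analysis drivers run the
36-scenario sweep at n = 10⁵ (≈ 30 s on one core), which leaves every
non-extreme cutoff with thousands of subjects per cell; the acceptance
properties (attenuation ordering with non-overlapping CIs, U-shape,
inflection-point overestimation, differential-misclassification
direction and its null, parameter recovery) are asserted at the full
n = 10⁶ on a shared base draw. Stochastic checks use explicit
Monte-Carlo standard errors: moments within 3–4 SE of their analytic
values, sensitivity/specificity within 3 SE of bivariate-normal
quadrature (the joint law of (X₁, W₁) is Gaussian with correlation
1/√(1+σ²)), empirical AUC within 3 Hanley–McNeil SE of the
quadrature-trapezoid value. Trend checks that are only asymptotic
(sensitivity non-increasing in the cutoff) exclude cutoffs whose truth
denominators are too small for the slack to dominate the noise.

## What the generator does and does not emulate

It emulates: the correlation structure and error model of two
environmental exposures, a realistic gestational-age distribution with
sex shift, rounding and inclusion, three exposure-response geometries,
and an integer severity outcome with a clinically-styled case cutoff.
It does not emulate: confounding (all covariates are mutually
independent by construction, so the adjustment variables are included
for realism, not necessity), finite-sample sampling error (analyses use
the whole cohort — instabilities at extreme cutoffs are structural, not
sampling artifacts), fetal-loss selection, measurement-error in the
outcome beyond rounding, or the empirical severity-score distribution
of any real cohort. Passing tests therefore demonstrate the internal
logic of categorization bias under clean conditions, not the magnitude
of that bias in any particular real study.

## Known limitations

* Absolute ORs and prevalences are functions of the synthetic severity
  transform; only their comparative geometry is meaningful.
* The `β₄ = +0.1` gestational-age coefficient is taken as configured
  even though a positive sign (later birth, higher severity) is
  epidemiologically debatable; it is config-overridable.
* Wald intervals are poor near separation; flagged points should be
  treated as "not estimable", not as wide-interval estimates.
* The threshold/saturation discontinuity at the inflection point is a
  modeling choice inherited with the scenario definitions; a continuous
  piecewise-linear variant would change curve shapes near −1 SD.
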
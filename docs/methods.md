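# Methods

## Model

The health process is a three-state illness–death model with recovery:
disability-free (0), disabled (1), dead (2, absorbing).  Time runs in
steps of h = 1/12 year; one month is the finest dated unit anywhere in
the package (births and deaths carry month/year, interview dates are
rounded to the nearest whole month of age, with days ≥ 16 rounding up).
Within each step, the probabilities of leaving the current transient
state are multinomial-logistic in exact age (years) and dichotomous
baseline covariates, with staying as the zero-logit reference; the death
row of every step matrix is exactly (0, 0, 1).  Four transitions carry
parameters — disability onset (0→1), recovery (1→0), and death from each
transient state — each with an intercept, an age slope per year, and one
coefficient per active covariate.  Covariates are time-invariant baseline
values.

The chain is "embedded": transition probabilities over an observation
interval are ordered products of the one-step matrices, each evaluated at
the age attained at the start of its step.  This marginalises whatever
happened between waves, so interval censoring of disability transitions
and skipped or unknown-state waves are handled exactly — an unknown wave
only lengthens the interval and provably never changes the likelihood
(tested).

## Likelihood

Each individual contributes, per consecutive pair of known-state waves,
the log of the corresponding interval-probability entry.  An exactly
dated death in month *m* is modelled as the transition taken during month
*m*: the contribution is Σ_s P(last known state → s, up to month
*m*) · p_{s,2}(month *m*) over transient *s*, i.e. survival times that
month's one-step death probability.  A wave and a death in the same month
resolve as wave-then-death.  A record whose only information is a death
has no definable contribution and is rejected (the fitter drops and
counts such records).  Because death is absorbing, all products are taken
in the 2×2 transient submatrix.

The kernel collapses episodes that are identical in (covariate pattern,
months, states) with multiplicity weights — on fully observed monthly
data this reduces the likelihood to an ordinary multinomial logit per
origin state, which is the module's primary correctness anchor: the fit
agrees with a direct `statsmodels` MNLogit on the (state, next-state)
records to ~1e-9 per coefficient.  The gradient is analytic (an adjoint
forward/backward sweep per episode, numba-compiled); it matches numerical
differentiation to ~1e-7.

Fitting: L-BFGS-B from crude initial values (aggregate transition
frequencies converted to logits; slopes and covariate effects start at
zero), followed by up to four Newton polish steps using the numerically
differentiated observed information (central differences of the analytic
gradient, step 1e-5·(1+|θ|)).  Age is internally centered (default 70
years) for conditioning; reported coefficients are de-centered, and the
covariance is transformed accordingly where needed.  Convergence requires
the optimizer to report success or the score max-norm to fall below
1e-5 per observation weight; non-convergence and coefficients reaching
the ±15 separation guard are flagged, never silent.  Identifiability is
checked up front: at least one observed 0→1 pair, one 1→0 pair and one
death, with the missing transition named in the error.

## Expectancies

Occupancy probabilities are iterated monthly from the target age x to a
closing age (default 115; transient mass left there is below ~1e-3 for
the default hazards and is logged on every estimate).  Expectancies use
the trapezoid rule — half weight on the first and last occupancy point —
so in the constant-hazard zero-disability limit TLE equals the geometric
closed form s/(12(1−s)) plus exactly h/2, the half-step that accounts for
the part of the death month actually lived.  The microsimulation oracle
applies the same integration rule to simulated paths, making the
matrix-product and Monte-Carlo estimators equal in expectation; they
agree within Monte-Carlo error at 100,000 paths.

Default weighting is "disability-free at age x" (unit mass on state 0),
because the emulated cohorts exclude baseline disability; a
model-prevalence mode (forward iteration from an anchor age, default
x − 20, with death renormalised out) is provided for comparability with
health-expectancy software that reports population-implied mixes, and a
"disabled" starting mode completes the set.  Tables label the mode.

Uncertainty: parametric bootstrap by default (B = 1000 draws from
N(θ̂, Σ̂), SD as SE, 2.5/97.5 percentiles as CI; seeded), with the delta
method (central-difference gradients through Σ̂, normal CIs) as the
cross-check — the two agree within a few percent on well-conditioned
fits, and the delta SEs match the empirical sampling SD of the estimates
in simulation.  A non-PSD covariance fails loudly with an opt-in
nearest-PSD repair.

Step length is configurable through `steps_per_year`; refining month →
week shifts the destination logits by log(12/52) (the embedded-chain
rescaling) and changes default-scenario expectancies by < 0.08 year,
within the 0.1-year stability margin asserted in the tests.

## Contrasts and reporting

Profile losses/gains are B − A differences (A = favourable reference, so
losses are negative) tested with a two-sample Z-test using independent
SEs, √(SE_A² + SE_B²) — the framing appropriate for separate groups and
the one under which the published loss rows reconstruct from the printed
group intervals (width/3.92 → SE).  Under the null (two groups simulated
from identical parameters, fitted separately) the test rejects at ~5%.
For profiles evaluated on one fitted model a correlated-delta variant
(SE from (g_B − g_A)ᵀΣ(g_B − g_A)) is provided and labelled in output.
No multiple-testing adjustment is applied across contrast rows.  The
normal quantile 1.96 is used for all 95% intervals.

Education is supported both as a stratification variable (separate fits
per stratum — the pipeline default for expectancy tables, mirroring the
published table layout) and as a model covariate (the pooled fit behind
the RRR table).  Neither is asserted to be what the original analysis
did; both are exposed.

## Synthetic cohorts

The generator emulates a two-cohort Australian women's panel with
registry-linked deaths: birth years 1921–26 (baseline age 70–75) with six
3-yearly waves then ten six-monthly waves over 20 years, and 1946–51
(baseline age 45–50) with a first follow-up after two years then 3-yearly
waves; published baseline prevalences (e.g. obesity 13.4% vs 19.1%, high
education 29.1% vs 50.3%); interview dates jittered uniformly ±45 days
around schedule (configurable off) to exercise unequal intervals; wave
non-response (default response 0.95; baseline always observed, and
non-responded waves are omitted by default, with an option to keep them
as unknown-state records); exactly dated death months censored at the
individual's end of follow-up.  Everyone starts disability-free, matching
the baseline-disability exclusion.

Default hazards are chosen once as demographically plausible for an older
female cohort: one-month death probability ~8·10⁻⁴ at age 70 from the
disability-free state, mortality doubling every 7–8 years, disability
onset ~2%/year at 70 rising with age, recovery ~9%/year declining, a
roughly four-fold mortality excess while disabled, and covariate effects
in the expected directions (obesity mainly on onset, RRR ≈ 2.2; smoking
mainly on mortality; exercise protective).  Under these defaults ~74% of
a 1921–26-style cohort dies within follow-up, close to the ~67% of the
emulated study.

What the generator does not emulate: SF-36 item-level responses (the
preprocessing tests carry their own item fixtures), household/cluster
structure, covariate drift over time, sampling weights, and
state-dependent non-response.  Passing tests therefore demonstrate
correctness of the estimators under the assumed model and survey design,
not robustness to informative missingness or measurement error in real
surveys.

## Validation experiments (study conditions)

* Oracle equivalence: n = 5000, 10 years of fully observed monthly waves,
  one covariate; the follow-up length is the package's choice (the
  comparison is exact for any horizon).
* Wald coverage: 200 replicates of n = 2000 with 8 three-yearly waves,
  default jitter and non-response; every coefficient's 95% CI covers the
  truth with empirical rate in [0.90, 0.98] (observed min ≈ 0.92).
* Null calibration: 200 replicates of two independent arms, n = 1000
  each, age-only model; DFLE contrast rejection rate at α = 0.05 observed
  ≈ 0.045.
* Microsimulation: 100,000 paths, best-lifestyle profile at age 70.

## Numerical choices and degenerate inputs

Softmax rows are computed max-shifted, so step matrices are finite and
row-stochastic for any finite logits; episode probabilities are floored
at 1e-300 inside the kernel to survive wild line-search steps.  Zero-
length intervals return indicators.  Duplicate wave months keep the first
observation.  SF-36 physical functioning is scored to 0–100 as
(raw − 10)/20 × 100 (the standard transform; the source's "1–100" is
treated as a typographical variant), with half-scale person-mean
imputation (score missing when more than five items are missing) — the
missing-item rule is a documented assumption, standard practice but not
stated by the source study.  Disability requires both a score strictly
below 40 and needing regular help; boundary cases (score exactly 40, BMI
exactly 18.5) fall on the lenient side by the strict inequalities.
Exclusion reasons are attributed by fixed priority (disability →
underweight → missing covariates) so tallies are deterministic and
partition the excluded set.

## Known limitations

No time-varying covariates, frailty, or continuous-time intensity
parameterisation; no Sullivan-method estimator; no decomposition of
expectancy differences into transition-specific contributions; the
parametric bootstrap assumes approximate normality of θ̂; absolute
expectancy levels from the restricted source data are not reproducible —
the published-value checks rest on contrast arithmetic and the synthetic
property suite.
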
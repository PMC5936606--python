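# Methods

## Model

Two 3-category outcomes per mother, hospitals as clusters.  Each outcome
follows a baseline-category logit against a fixed reference (`term`,
`normal`); both non-reference contrasts of an outcome share one hospital
random intercept, so each hospital contributes a single shift per outcome:

    log P(y1 = c | u1) / P(y1 = ref) = u1 + ω_c + x'α_c
    log P(y2 = c | u2) / P(y2 = ref) = u2 + θ_c + z'β_c

Slopes are category-specific (α_preterm ≠ α_postterm): the two contrasts of
one predictor are genuinely different epidemiological quantities (e.g. a
factor can raise preterm risk and leave postterm unaffected).

The pair (u1, u2) follows a bivariate Bridge law.  Each margin is
Bridge(φ_k) with density `f(u; φ) = (1/2π) sin(φπ)/(cosh(φu) + cos(φπ))`,
quantile `Q(p) = (1/φ) log[sin(φπp)/sin(φπ(1−p))]` and variance
`(π²/3)(φ⁻² − 1)`.  The defining property — and the reason to prefer it
over normal random effects — is the marginalization identity
`∫ expit(u + η) f(u; φ) du = expit(φη)`: population-averaged and
hospital-specific coefficients differ only by the factor φ, so `exp(coef)`
keeps one odds-ratio interpretation.  The identity is exact for a binary
logit; for the 3-category model it is exact conditional on the
baseline-category contrast structure, and the package's tests exercise it
in the binary collapse (a cluster-ignoring logistic fit recovers φ times
the conditional slope).

The two margins are coupled by a Gaussian copula with correlation
ρ ∈ (−1, 1): (z1, z2) bivariate standard normal with correlation ρ and
u_k = Q_k(Φ(z_k)).  This preserves the Bridge margins exactly and
parameterises the outcome association with a single interpretable number;
ρ = 0 gives independent sub-models, and the likelihood then factorises
exactly (a property the tests assert).  The copula CDF uses the closed-form
Bridge CDF `F(u) = 1 − 1/(2φ) + (1/πφ) arctan[(e^{φu} + cos φπ)/sin φπ]`,
obtained by integrating the density; the test suite verifies it against
independent quantile bisection and the derivative relation F' = f.

## Likelihood and quadrature

The cluster likelihood integrates the product of all members' category
probabilities over (u1, u2).  The integral is evaluated in the copula's
independent normal coordinates t = (t1, t2) (u1 = Q1(Φ(t1)),
u2 = Q2(Φ(ρt1 + √(1−ρ²)t2))), where the prior is exactly Gaussian.

Quadrature is *cluster-adaptive*: for every cluster the log-integrand's
mode and curvature are found by a damped Newton iteration with analytic
derivatives (chain rule through u(t)), and a product rule is centred and
scaled there with the per-dimension standard deviation capped at 1.2 (the
prior scale).  The default rule places equally spaced (trapezoid) nodes
over mode ± 8 sd, 31 per dimension.  This departs from the classical
adaptive Gauss–Hermite choice deliberately: for smooth integrands with
Gaussian decay the trapezoid rule converges geometrically, and it resolves
the two-scale shape the integrand takes when φ is close to 1 (the Bridge
density is then a narrow spike with exponential flanks) far better.
Measured against a 121-node reference on 10 hospitals × 50 mothers, the
default grid is accurate to ~6e-7 per observation at φ = 0.95 and ~2e-7 at
φ = 0.6; an adaptive Gauss–Hermite rule (`QuadratureGrid(n, "hermite")`,
kept as an independent cross-check) is one to two orders of magnitude worse
at equal cost, and *non-adaptive* tensor rules fail outright because a
cluster with many members concentrates the integrand in a narrow off-centre
peak.  Rows are compressed to unique (cluster, covariates, outcome)
patterns with multiplicities, which makes simulation studies with
categorical covariates hundreds of times faster.

Heavy simulation studies use fewer nodes where the measured accuracy
permits: the recovery study runs at 15 nodes (error ~6e-4 per cluster at
its φ = 0.6 conditions, two orders below the parameter standard errors) and
the screening study at 21.

## Estimation

L-BFGS-B on an unconstrained parametrisation (slopes and thresholds free,
φ = expit(a) clamped to [1e-9, 1−1e-9], ρ = tanh(r)), finite-difference
gradients, relative log-likelihood tolerance 1e-11.  Starting values are
deterministic: slopes zero, thresholds log(n_c/n_ref)/0.7, φ = 0.7, ρ = 0.
A jittered multi-start (`n_starts`) is available but defaults to one start:
in development checks across jittered starts the optimiser always reached
the same optimum, and single starts keep the replicate studies affordable.
Convergence is the optimiser's relative-change criterion; the final
projected-gradient norm is reported in the diagnostics rather than
hard-thresholded, because finite-difference noise at |loglik| ~ 1e3–1e4 is
itself of order 1e-1.

Standard errors are observed information: a central-difference Hessian at
the optimum (relative step 1e-3), inverted on the unconstrained scale.
Odds-ratio CIs use endpoint transformation exp(b ± 1.959964·se); p-values
are two-sided Wald.  φ and ρ intervals are transformed from the
unconstrained scale.  `fix_rho` profiles the copula correlation (ρ = 0
reproduces two independent univariate fits, asserted to 1e-4).

The screening stage fits one single-predictor multilevel model per
candidate and outcome (same Bridge machinery, 1-D quadrature) and compares
it with the intercept-only model by a 2-df likelihood-ratio test — the two
contrasts of a predictor are tested jointly, since a single predictor-level
p-value is needed.  A predictor enters the joint model when p < 0.20 for at
least one outcome (per-outcome candidate sets are kept as well); univariate
non-convergence marks the predictor "undetermined" and excludes it with a
log entry rather than silently.

## Synthetic cohorts

The generator replaces the unavailable raw cohort and defines the study
conditions: 30 hospitals (the true number is unpublished; tens of
university-supervised centres is the plausible magnitude) with lognormally
dispersed sizes totalling 4415 mothers.  Covariates are drawn independently
with marginals matching the published summary tables — mother's age
truncated-Normal(29.18, 5.35) on [15, 50], BMI truncated-Normal(25, 5) on
[15, 45], SES Normal(0, 2), and binaries at the published prevalences
(preeclampsia 0.053, ART 0.075, multiple pregnancy 0.014, parity ≥ 2 0.511,
male infant 0.507, graduate mother 0.327, ...).  Planted effect sizes equal
the published adjusted odds ratios (preeclampsia 4.14 and multiple
pregnancy 18.04 on preterm, multiple pregnancy 17.35 on LBW, male sex 1.78
on macrosomia, ...); the two postterm entries whose printed intervals are
internally inconsistent are planted as null.  Default random-effect law:
φ1 = φ2 = 0.95 (latent ICC ≈ 0.10, moderate between-hospital
heterogeneity) and ρ = 0.6 (strong outcome association).

Thresholds are never tuned: they solve the marginal prevalence equations —
category probabilities averaged over the covariate sample and the Bridge
law equal the published prevalences — by root-finding started at the
marginalization-identity value.  With all slopes zero this reproduces the
published prevalences exactly in expectation (verified against dense
quadrature and Monte Carlo).

What the generator does **not** emulate: covariate correlations (none are
published; columns are independent), missingness, measurement error, or the
questionnaire instrument.  Passing tests therefore demonstrate correctness
of the estimator under the model's own assumptions, not robustness to
misspecification.

## Validation studies and problem sizes

* Recovery: 100 replicates at 50 hospitals × 100 mothers, one binary
  predictor with planted preterm log-OR ln 4, φ = 0.6, ρ = 0.5; the 95%
  Wald CI covers truth in ≈ 95 of 100 replicates.
* Screening calibration: 200 null simulations at 30 × 50; the P < 0.20
  entry rate for a single outcome sits near 0.19.
* Likelihood oracle: cluster likelihoods agree with plain 1e6-draw
  Monte-Carlo copula integration within 3 MC standard errors.
* Round trip: a 50-hospital × 6000-mother binary-predictor cohort at the
  generator defaults is refit and every slope lands within 3 Wald SEs of
  its planted value, with φ recovered within 0.1.

These sizes are the package's validation design; larger versions only
shrink Monte-Carlo noise.

## Numerical details and edge cases

* `cosh(φu) + cos(φπ)` is evaluated as `2sinh²(φu/2) + 2sin²((1−φ)π/2)`
  (stable as φ → 1) with an asymptotic branch for |φu| > 600; copula tails
  use `ndtr(−z)` rather than `1 − ndtr(z)`.
* Degenerate designs fail loudly: constant or collinear predictor columns
  raise errors naming the columns; unknown category labels name row and
  column; an all-missing column is an error, not a silent drop.
  Complete-case filtering logs the dropped-row count.
* Zero-margin rows/columns are dropped from chi-square tests with a warning
  and adjusted df; no continuity correction is applied anywhere (the plain
  Pearson statistic is what reproduces the published 940.308).
* Rendered tables round to the conventional 2 decimals (odds ratios) and
  1 decimal (percentages); machine outputs keep full precision and are
  byte-deterministic given the seed.

## Known limitations

* Quadrature error grows with cluster size when φ is very close to 1;
  at the default 31 nodes the total log-likelihood bias on a 4415-mother
  cohort is ~1e-2, negligible for slopes but visible in the third decimal
  of φ̂.  Raise `nodes` if that matters.
* The Wald intervals for φ near its upper boundary are asymmetric on the
  constrained scale and can be anti-conservative in small cluster counts.
* Contrasts with no observed events (e.g. postterm in small cohorts)
  diverge to the boundary with unusable standard errors; the report marks
  them rather than suppressing them.
* Screening uses Bridge random intercepts in the univariate models for
  internal consistency; with another random-effect law the univariate
  p-values would differ slightly.
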
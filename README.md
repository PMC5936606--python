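# bridgejoint

Joint multilevel modelling of two correlated 3-category perinatal outcomes —
gestational-age class (preterm / term / postterm) and birth-weight class
(LBW / normal / macrosomia) — for cohorts of mothers nested in hospitals.
The package is aimed at perinatal epidemiologists and biostatisticians who
want adjusted odds ratios for both outcomes *jointly*, with hospital-level
clustering handled by random intercepts that keep the odds-ratio
interpretation intact.

## The model

For mother *j* in hospital *i*, each outcome follows a baseline-category
(nominal) logit with a hospital random intercept shared by both
non-reference contrasts:

```
log P(y1ij = c) / P(y1ij = term)   = u1i + ω_c + x'ij α_c      c ∈ {preterm, postterm}
log P(y2ij = c) / P(y2ij = normal) = u2i + θ_c + z'ij β_c      c ∈ {LBW, macrosomia}
```

The pair (u1i, u2i) follows a **bivariate Bridge distribution**: each margin
is Bridge(φk) with density
`f(u; φ) = (1/2π) · sin(φπ) / (cosh(φu) + cos(φπ))`, and the two margins are
coupled through a Gaussian copula with correlation ρ, which induces the
association between the two outcomes.  The Bridge law is the random-effect
distribution for which integrating out the intercept preserves the logistic
form — `∫ expit(u + η) f(u; φ) du = expit(φη)` — so `exp(α_c)` has the same
odds-ratio reading within and between hospitals, unlike normal random
effects.  φ ∈ (0, 1) controls heterogeneity (variance `(π²/3)(φ⁻² − 1)`,
degenerate at φ = 1).

Estimation is maximum likelihood: per-cluster integrals over (u1, u2) are
computed by cluster-adaptive quadrature in the copula's normal coordinates,
and standard errors come from the observed information.  Around the joint
fit the package reproduces the standard workflow: descriptive tables with
tests, univariate multilevel screening at P < 0.20, and odds-ratio tables
with 95% Wald intervals.  Because no raw cohort of this kind is publicly
deposited, a synthetic-data generator emulates the study conditions (30
hospitals, 4415 mothers, published covariate marginals and outcome
prevalences 5.5/94.0/0.5% and 4.8/92.4/2.8%).

## Worked example

```python
import numpy as np, pandas as pd
import bridgejoint as bj

spec = bj.ModelSpec(predictors1=["preeclampsia"], predictors2=["preeclampsia"])
truth = bj.ParameterVector(
    omega=[-2.0, -3.0], alpha=[[np.log(4.0)], [0.0]],
    theta=[-2.2, -3.2], beta=[[np.log(3.0)], [0.0]],
    phi1=0.7, phi2=0.7, rho=0.5,
    names1=["preeclampsia"], names2=["preeclampsia"])
rng = np.random.default_rng(0)
cov = pd.DataFrame({
    "hospital": np.repeat([f"H{i}" for i in range(40)], 120),
    "preeclampsia": np.where(rng.random(4800) < 0.3, "Yes", "No")})
cohort = bj.generate_outcomes(cov, truth, spec, seed=1)

fit = bj.JointBridgeMultinomial.from_dataframe(cohort, spec, nodes=21).fit()
print(fit.summary())
```

prints

```
Joint multilevel baseline-category logit with Bridge random intercepts
========================================================================
outcomes: gestational_age (ref 'term'), birth_weight (ref 'normal')
n_obs: 4800    n_clusters: 40    log-likelihood: -5336.1706
converged: True

Odds ratios (Wald, level 95%)
        outcome             contrast    predictor    coef     se     OR  ci_low  ci_high      p
gestational_age      preterm vs term preeclampsia  1.3822 0.0834 3.9837  3.3832   4.6907 0.0000
gestational_age     postterm vs term preeclampsia -0.0663 0.1735 0.9358  0.6661   1.3149 0.7024
   birth_weight        LBW vs normal preeclampsia  1.1112 0.0886 3.0379  2.5537   3.6138 0.0000
   birth_weight macrosomia vs normal preeclampsia -0.1357 0.1815 0.8731  0.6118   1.2460 0.4545

Random-intercept law (bivariate Bridge, Gaussian copula)
parameter  estimate  ci_low  ci_high
     phi1    0.7938  0.6988   0.8647
     phi2    0.7426  0.6502   0.8175
      rho    0.5959  0.3364   0.7713
```

The planted preterm odds ratio 4.0 is recovered as 3.98 (95% CI 3.38–4.69),
the LBW odds ratio 3.0 as 3.04, and the copula correlation 0.5 as 0.60 with
a CI covering truth.  The full shell workflow is available as
`bridgejoint run --config cfg.yaml --out outdir` (stages `simulate`,
`describe`, `screen`, `fit`, `report` also run individually and compose via
files on disk).

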
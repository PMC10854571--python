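# zbln-aft

Parametric survival modelling for metastatic lung-cancer cohorts:
an accelerated failure time (AFT) regression whose baseline is the
**Zografos–Balakrishnan log-normal (ZBLN)** distribution, with log-normal
AFT, Weibull AFT and Cox proportional-hazards comparison arms, a full
internal-validation toolkit, and a synthetic SEER-like cohort generator so
that every stage is testable without restricted registry data.

## The scientific problem

Patients whose lung or bronchus cancer has spread to bone and/or brain
have short, strongly right-skewed cause-specific survival (median on the
order of months). The Cox model — the default in this literature —
assumes proportional hazards, an assumption such cohorts typically
violate. AFT models act on time itself,

    T = T0 · exp(x'β),        log T = μ0 + x'β + σ·W,

so a coefficient β has a direct clinical reading through the
**acceleration factor** AF = exp(β): AF > 1 means the level lengthens
survival relative to its reference level, AF < 1 shortens it.

The flexibility of the fit lives in the baseline law of W. The ZBLN
distribution generalizes the log-normal with a gamma-generator shape
`a > 0`: if `g, G` are the log-normal(μ, σ) density and distribution
function and `H(t) = −log(1−G(t))` its cumulative hazard,

    f(t) = g(t) · H(t)^(a−1) / Γ(a),     F(t) = P(a, H(t)),

with `P` the regularized lower incomplete gamma function. Equivalently
`H(T) ~ Gamma(a, 1)`, which gives exact sampling and closed-form
quantiles; `a = 1` recovers the plain log-normal exactly.

The package implements, as importable library code under `src/zbln_aft/`:

- `cohort`: typed cohort tables, CSV/JSON I/O, reference-level dummy
  coding, 70/30 train/validation splitting, re-censoring;
- `zbln`: the ZBLN law (density, distribution/survival, quantiles, exact
  sampler, censored univariate MLE);
- `aft`: right-censored AFT likelihood with analytic gradients for the
  ZBLN / log-normal / Weibull families, profile-likelihood fitting,
  observed-information standard errors, AIC/BIC, acceleration factors,
  Wald tests;
- `coxph`: Cox PH fit (Efron ties), Schoenfeld-residual proportionality
  test, L1-penalized Cox feature selection with cross-validated
  partial-likelihood deviance;
- `validation`: Harrell C-index, Kaplan–Meier, equal-count calibration
  tables, RMSE of predicted median survival;
- `simulate`: the SEER-like generator (published covariate marginals,
  ZBLN-AFT time mechanism, administrative censoring at 36/60 months);
- `pipeline` + `cli`: the end-to-end study and a `zbln-aft` command.

Numbered drivers under `analysis/` run the study narrative
(simulate → fit/compare → recover) and write tables under `results/`.

## Worked example

```python
from zbln_aft import (AFTModelSpec, acceleration_factors, default_scenario,
                      fit_aft, generate_cohort, split_cohort, validate_model)

cohort = generate_cohort(default_scenario(horizon=36, n=5000, seed=7))
train, test = split_cohort(cohort, 0.7, seed=7)

covariates = ("age", "race", "gender", "treatment", "histology",
              "primary_site", "grade", "metastases")
fit = fit_aft(train, AFTModelSpec("zbln", covariates))
print(f"log-likelihood {fit.log_likelihood:.1f}  AIC {fit.aic:.1f}  "
      f"a {fit.ancillary['a']:.2f}  sigma {fit.ancillary['sigma']:.2f}")

af = acceleration_factors(fit)
print(af[af.variable == "treatment"].to_string(index=False))

report = validate_model(fit, test, horizon=36)
print(f"held-out C-index {report.c_index:.3f}  RMSE {report.rmse:.1f} months")
```

prints

```
log-likelihood -9922.4  AIC 19892.9  a 1.94  sigma 1.29
 variable               term  estimate    AF             p
treatment No Treatment (Ref)       NaN 1.000           NaN
treatment        Monotherapy -0.387810 0.679  1.263330e-04
treatment    Bimodal Therapy  1.219631 3.386 1.225491e-165
treatment   Trimodal Therapy  1.152555 3.166  2.545496e-51
held-out C-index 0.668  RMSE 7.4 months
```

Reading: the generator's true baseline (a = 2, σ = 1.3) is recovered; the
multimodal-treatment acceleration factors ≈ 3.2–3.4 say those patients'
survival times run about three times longer than untreated patients',
all else equal; the held-out concordance of ~0.67 matches what a
correctly specified model can achieve at these effect sizes. The same
study runs from the shell:

```sh
zbln-aft simulate --horizon 36 --n 5000 --seed 7 --out cohort.csv
zbln-aft run --config study.json
```

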
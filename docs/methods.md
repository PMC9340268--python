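# Methods

## Data-generating mechanism

Each simulated study is a cohort of n = 47,770 individuals with 11 binary
baseline predictors and a binary 20-year all-cause death outcome.  The
covariates are drawn as independent Bernoulli variables; the outcome is
drawn from a logistic model

    logit P(died) = beta0 + sum_j beta_j x_j + ln(or_m) * diet
                    + ln(or_w / or_m) * diet * woman

so that the adjusted diet odds ratio is `or_m` among men and `or_w` among
women.  The three scenario presets hold `or_m = 0.75` and vary
`or_w` over {0.70, 0.65, 0.60}; a `null` preset (`or_m = or_w = 1`) is
provided for type-I-error calibration.  Column order is fixed (diet,
woman, then the nine adjusters alphabetically) and written into every
cohort CSV header; no survival-time structure is generated — the outcome
is a single end-of-follow-up death indicator, matching the logistic
analysis it feeds.

### Default predictors

| predictor        | prevalence | main-effect OR |
|------------------|-----------:|---------------:|
| diet             |      0.25  | (from scenario)|
| woman            |     0.4824 |           0.65 |
| age_65_plus      |      0.45  |           9.0  |
| bmi_20_plus      |      0.95  |           0.70 |
| cohabiting       |      0.75  |           0.80 |
| high_education   |      0.35  |           0.80 |
| moderate_alcohol |      0.25  |           0.85 |
| sleep_7h         |      0.35  |           0.85 |
| small_waist      |      0.75  |           0.80 |
| smoking_ever     |      0.45  |           1.80 |
| walking_20min    |      0.55  |           0.75 |

The woman prevalence is pinned to the emulated cohort's sex ratio
(23,045/47,770) and enforced as a model invariant.  The remaining values
are surrogates: the real cohort's joint covariate distribution is not
public, so the defaults were chosen once against three calibration
contracts and then frozen:

1. **Marginal death risk** 21,978/47,770 = 0.4601 — guaranteed by
   intercept calibration (below), realized cohort death fractions land
   within 0.01 of it.
2. **Interaction-coefficient standard error ≈ 0.049 at n = 47,770.**
   This is the quantity that makes the power ladder reproducible: a
   two-sided 5% Wald test with SE = 0.049 has power
   Phi(|delta|/SE − 1.96) ≈ 0.28, 0.83 and 1.00 against the three
   interaction effects delta = ln(or_w/or_m) ∈ {−0.069, −0.143, −0.223}.
   `implied_interaction_se` measures it empirically; the shipped model
   gives ≈ 0.0496 (contract band [0.044, 0.055]).  The diet prevalence
   (0.25, i.e. roughly a top-quartile diet-quality indicator) is the
   dominant lever here, since SE ∝ 1/sqrt(prevalence) when the exposed
   group is the smaller one.
3. **Discrimination** (in-sample logistic AUC) near 0.80, treated as a
   soft goal; the strong age effect (65+ vs younger over 20 years of
   mortality follow-up, OR 9) carries most of it, and the shipped model
   reaches ≈ 0.79.

Independence of the covariates is a deliberate simplification: real
lifestyle factors are correlated, and dichotomized.  Passing tests
therefore demonstrate estimator behaviour under a clean, favourable
mechanism — they say nothing about misspecification, confounded or
continuous covariates, or non-logistic outcome processes.

### Intercept calibration

The mean risk is strictly increasing in beta0, so beta0 is found by
Brent root-finding of `mean(sigmoid(offset + beta0)) − target` on a fixed
calibration covariate sample (200,000 draws, dedicated seed), bracketed
at ±30 log-odds with a clear error when the target is unattainable.
Calibration is per scenario because the diet effect shifts the marginal
risk slightly.

### Seeding

One base seed per study.  Replication r of a scenario uses a child seed
derived from a `SeedSequence` keyed on (base seed, CRC32 of the scenario
name, r), so any replication is reproducible in isolation, scenarios are
mutually independent, and the first R replications of a longer run are
exactly the R-replication run.  All derived seeds are kept below 2^31.

## Estimators

**Logistic.**  Exact maximum likelihood (Newton-Raphson via statsmodels,
parameter-change tolerance 1e-8, no regularization) on the design
(intercept, 11 main effects, diet×woman product).  The covariance is the
inverse observed information.  Perfect separation or a singular design is
flagged as non-converged with a diagnostic rather than raised; the
harness excludes such replications from all summary fractions and reports
the exclusion count (none occur under the default mechanism at
n = 47,770).  The Wald test is two-sided at alpha = 0.05 throughout.

**Boosted trees + SHAP.**  XGBoost with the binary logistic objective,
single thread, seeded.  Hyperparameters (number of trees, depth, minimum
child weight; learning rate fixed at 0.1) are tuned by 2-fold stratified
cross-validation on held-out log-loss, with exact ties broken toward the
simplest model (fewest trees, then smallest depth, then smallest child
weight).  Tuning happens once per scenario on replication 0's cohort and
is reused across that scenario's replications; per-replication tuning is
a config switch.  The default grid is {50, 100, 200} × {2, 3, 4} ×
{1, 5, 10}; a 4-point `SMALL_GRID` spanning the same depth range is used
where the full grid would dominate runtime.

SHAP values are computed by the exact tree-path-dependent algorithm on
the margin (log-odds) scale with no background dataset, in-sample on the
full training cohort.  Local accuracy — base value plus all attributions
equals each individual's raw margin — is verified against the model's
margins at tolerance 1e-4 every time a matrix is computed, and an
exhaustive Shapley enumeration over feature coalitions serves as an
independent oracle for single-stump models in the tests.

The SHAP-based stratum odds ratio averages the *diet-feature* SHAP
column within each diet×sex cell and exponentiates the within-sex
difference.  The plausible alternative — averaging each individual's
total SHAP across features — would mix in the attributions of every
adjuster and no longer isolate a diet effect; the dependence-plot view
(phi_diet against diet status, colored by sex) corresponds to the
cell-mean reading.  Ties S-OR_W = S-OR_M, possible with discrete trees,
are counted against the estimator (not a correct ordering).

## Direction convention

A genuine protective interaction makes the diet odds ratio *smaller*
(more protective) among women.  Informally this is often phrased as the
benefit being "greater among women"; numerically the criterion
implemented everywhere is **OR_W < OR_M**, for both the logistic and the
SHAP odds ratios.

## Harness and metrics

Fast mode runs only the logistic estimator (~0.1 s per replication);
full mode adds boosting + SHAP (~3 s per replication at n = 47,770).
Power is the fraction of converged replications with Wald p < alpha;
sign sensitivity the fraction with OR_W strictly below OR_M; bias the
mean interaction estimate minus ln(or_w/or_m); percentiles (2.5/50/97.5)
are computed on the odds-ratio scale per sex with linear interpolation.
Replication records round-trip exactly through CSV
(`save_results`/`load_results` use round-trip float parsing).

Problem sizes used by the shipped study-level checks and the acceptance
script: 200 replications per scenario for the power and logistic
sign-sensitivity ladders, 1,000 for the bias of the interaction
estimator, 100 full-mode replications per scenario for the SHAP sign
sensitivities (with the 4-point tuning grid), and 500 null-scenario
replications for type-I-error calibration, all at the full cohort size
n = 47,770.  Observed fractions at these sizes carry binomial Monte-Carlo
error of roughly ±2–4 percentage points, which is the tolerance the
study-level tests apply.

## Numerical choices and degenerate inputs

- Prevalences must lie strictly in (0, 1); zero/one prevalence and
  non-finite coefficients are rejected at construction.
- Single-class outcomes are rejected by both estimators; empty diet×sex
  cells abort the SHAP odds ratio with the offending cell named.
- Bisection tolerance for intercept calibration is 1e-12 on beta0 with a
  1e-6 check on the realized calibration-sample risk.
- Histogram panels fix 40 bins on the log-OR axis so scenarios are
  visually comparable; figures are SVG with a fixed hash salt and no
  embedded date, so identical inputs give identical files.

## Known limitations

- Independent Bernoulli covariates understate the collinearity of real
  lifestyle data; the interaction SE contract compensates at the level
  of the target quantity but not of the joint distribution.
- SHAP odds ratios are marginal-flavoured quantities derived from a
  conditionally specified generator, so their "bias" has no sharp
  definition here and none is reported; no confidence intervals are
  provided for them (their sampling distributions are far from
  log-normal).
- The empirical-cohort analysis that motivated the defaults cannot be
  reproduced (restricted individual-level data); `analyze` accepts any
  user cohort CSV with the required schema instead.
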
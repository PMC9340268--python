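# interactsim

Monte-Carlo evaluation of **diet-by-sex interaction detection** in a large
prospective mortality cohort, comparing a classical logistic regression with
an explicit product term against gradient-boosted trees explained through
SHAP values.

## The scientific problem

In nutritional epidemiology the association between an exposure (here, a
healthy diet) and an outcome (20-year all-cause mortality) may differ across
levels of another factor (here, sex).  Two ways to look for such effect
modification:

1. **Logistic regression** with a product term.  With diet indicator $D$,
   woman indicator $W$ and adjusters $X_j$,

   $$\operatorname{logit} P(Y{=}1) = \beta_0 + \beta_D D + \beta_W W +
     \beta_{DW} D W + \textstyle\sum_j \beta_j X_j ,$$

   the stratum-specific adjusted diet odds ratios are
   $\text{L-OR}_M = e^{\beta_D}$ (men) and
   $\text{L-OR}_W = e^{\beta_D + \beta_{DW}}$ (women), and the interaction
   is tested with the two-sided Wald statistic
   $z = \hat\beta_{DW} / \widehat{SE}(\hat\beta_{DW})$.

2. **Boosted trees + SHAP.**  An XGBoost classifier with a logistic
   objective is trained *without* any specified interaction.  Exact
   tree-path-dependent SHAP values $\phi_{D,i}$ (log-odds scale) attribute
   each individual's predicted margin to the diet feature, and a SHAP-based
   adjusted odds ratio is formed per sex stratum $s$:

   $$\text{S-OR}_s = \exp\!\big(\overline{\phi_D}^{\,D=1,s} -
     \overline{\phi_D}^{\,D=0,s}\big).$$

   An interaction shows up as $\text{S-OR}_W \ne \text{S-OR}_M$ even though
   the model was never told about it.

The package generates synthetic cohorts emulating a pooled Swedish cohort
(n = 47,770; 23,045 women; 21,978 deaths over 20 years; 11 binary baseline
predictors) under three interaction scenarios — small
(OR$_M$ = 0.75 vs OR$_W$ = 0.70), moderate (0.75 vs 0.65) and large
(0.75 vs 0.60) — and measures, over replicated studies:

- **power**: fraction of replications with Wald $p < 0.05$;
- **sign sensitivity**: fraction in which the women-stratum OR is
  correctly estimated to be more protective (smaller) than the men's;
- **bias** of $\hat\beta_{DW}$ relative to $\ln(\text{OR}_W/\text{OR}_M)$;
- sampling-distribution percentiles of the stratum odds ratios.

## Worked example

Run 200 replicated studies of the moderate scenario (logistic estimator
only) from the command line:

```sh
interactsim run-study --reps 200 --scenario moderate --seed 11 --out demo
```

which logs

```
INFO interactsim: moderate: 200/200 replications
INFO interactsim: moderate: power=0.855 sign_lr=1.000 sign_shap=- bias=-0.0054 excluded=0
```

and writes `replications.csv`, `summary.csv`/`summary.json` and a
histogram of the per-sex sampling distributions.  Reading the summary:
85.5% of simulated studies rejected the no-interaction hypothesis at the
5% level (power); in every study the women-stratum OR was estimated below
the men's (sign sensitivity 1.00); the mean interaction coefficient was
within 0.006 of its true value ln(0.65/0.75); and the stratum odds-ratio
sampling distributions had (2.5th, 50th, 97.5th) percentiles
(0.71, 0.75, 0.81) for men and (0.61, 0.65, 0.69) for women — centered on
the generating values 0.75 and 0.65.

The same machinery is available as a library:

```python
from interactsim import (SCENARIOS, calibrated_model, HarnessConfig,
                         run_scenario, power, sign_sensitivity)

model = calibrated_model("moderate")      # intercept set so risk = 0.4601
results = run_scenario(model, SCENARIOS["moderate"], reps=200, base_seed=11,
                       config=HarnessConfig(mode="fast"))
print(power(results), sign_sensitivity(results, "logistic"))
```

Full mode (`HarnessConfig(mode="full")` or `--mode full`) additionally
trains the boosted model per replication, tunes its hyperparameters once
per scenario by 2-fold cross-validation, and records SHAP-based odds
ratios; `interactsim analyze cohort.csv` applies both estimators to any
user-supplied cohort CSV (binary predictor columns including `diet` and
`woman`, outcome column `died`).

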
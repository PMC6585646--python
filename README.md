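# simulelast

Panel-econometrics toolkit for a question that is circular by nature: richer
countries spend more on medicines, and public pharmaceutical spending may in
turn affect national income.  `simulelast` implements, as a tested and
reusable pipeline, the two-step instrumental-variables strategy used to break
that circle in country-year panels, together with the estimators,
diagnostics, robustness procedures and a synthetic-data generator that make
the whole pipeline verifiable by parameter recovery.

It is aimed at health economists and applied econometricians working with
long-format country x year tables (public pharmaceutical expenditure per
capita, GDP per capita, tourist receipts, optional controls), all in logs.

## The model

Two simultaneous fixed-effects equations, for country *i* and year *t*:

```
y_it = β x_it + μ'w_it + α_i + γ_t + ε_it        (expenditure equation)
x_it = δ y_it + μ'w_it + a_i + g_t + u_it        (income equation)
```

with `y` log public pharmaceutical expenditure per capita, `x` log GDP per
capita, `w` time-varying controls, and full sets of country (`α_i`, `a_i`)
and year (`γ_t`, `g_t`) effects.  β is the **income elasticity** of
pharmaceutical spending (β > 1 means medicines behave like a luxury good);
δ is the **reverse effect** of spending on income.  Because `y` and `x`
determine each other contemporaneously, least squares is inconsistent for
both.

**Step 1** instruments `x` with log international tourist receipts `z` (an
income shifter excluded from the expenditure equation) and estimates β by
fixed-effects 2SLS.

**Step 2** constructs the endogeneity-adjusted series

```
y*_it = y_it − β̂ x_it
```

— the residual variation in expenditure not driven by income — and uses it
as the instrument for `y` in the income equation, which purges the
simultaneity from δ̂.  Because `y*` depends on the estimated β̂, a
pairs-cluster bootstrap (resampling countries, rerunning both steps)
propagates the generated-instrument noise into the step-2 standard errors.

Around this core the package provides: two-way within-demeaning on
unbalanced panels, lag construction, balanced-panel extraction; classical /
HC1 / country-clustered variances; first-stage F, rank-LM
underidentification, Hausman FE-vs-RE and Durbin–Wu–Hausman endogeneity
diagnostics; Hadi forward-search multivariate outlier screening; IV quantile
regression by inverse-quantile grid search; and a simultaneous-system
simulator with ground truth for every oracle.

## Worked example

```python
from simulelast import (ModelSpec, SimulationConfig, fe_ols, fe_2sls,
                        full_diagnostics, generate_panel, two_step)

data, truth = generate_panel(SimulationConfig(seed=1))   # 136 countries x 12 years
spec = ModelSpec("log_pharma", endogenous=("log_gdp",), instruments=("log_tourism",))

ols  = fe_ols(ModelSpec("log_pharma", controls=("log_gdp",)), data)
iv   = fe_2sls(spec, data)
diag = full_diagnostics(spec, data, result=iv)
ts   = two_step(data, y="log_pharma", x="log_gdp", z="log_tourism",
                n_boot=199, seed=1)
```

prints (via `examples/02_income_elasticity_iv.py` and
`examples/03_reverse_effect_twostep.py`):

```
FE-OLS elasticity : 0.972 (0.076)
FE-2SLS elasticity: 1.416 (0.575)   [truth 1.4]
first-stage F = 19.05
step-1 elasticity beta_hat = 1.416
naive OLS reverse effect   = 0.120  (upward biased)
two-step reverse effect    = -0.066   [truth -0.09]
  analytic SE  = 0.0122
  bootstrap SE = 0.1066 (199 entity-cluster replicates, 0 failed)
```

Reading: naive OLS understates the elasticity (0.97 vs the true 1.4) because
the negative feedback δ < 0 pulls it down; 2SLS recovers it.  In the reverse
direction naive OLS even gets the *sign* wrong (+0.12 for a true −0.09) —
income-driven co-movement masquerades as a positive effect — while the
two-step estimate lands near the truth.  The bootstrap SE is ~9x the
analytic one: most of the step-2 uncertainty comes from β̂ inside the
constructed instrument.

`examples/` contains one short script per capability (simulation and
description, IV elasticity, two-step reverse effect, outlier screen,
quantile IV).  A thin CLI mirrors the pipeline:
`simulelast simulate|main|robustness|reverse|lags|splits|ivqr|twostep
--config cfg.json --out dir/`.

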
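# tvcc — time-varying exposure–outcome associations from case-control data

Standard (unmatched or frequency-matched) case-control studies are usually
analysed with a single logistic regression, which yields one odds ratio and
cannot tell you whether the effect of an exposure *changes over time*.  The
motivating question is vaccine-efficacy waning: in a case-control study of
infant BCG vaccination and tuberculosis, does protection (1 − HR) fade with
years since vaccination?

`tvcc` implements two estimators of a time-varying exposure effect from
ordinary case-control data, for epidemiologists and biostatisticians who
have exactly that data layout: one row per subject with case status, an
index time (event age for cases, interview/censoring age for controls), an
entry time (left truncation), a binary exposure, optional covariates and a
frequency-matching stratum.

**1. Period-wise logistic regression with control reuse.**  Within each of
L consecutive half-open time periods `[τ_lA, τ_lB)` the model

```
logit Pr(D_l = 1 | x, z) = δ_0l + δ_Xl x + δ'_Zl z
```

is fitted jointly over an expanded dataset: each case contributes one
record in its event period, and each control one record per period in which
it is *eligible*.  Four printed eligibility rules are implemented exactly
(definitions i–iv, comparing the control's entry time `T_E` and index time
`T_I` with the period limits); the recommended definition (i) lets a control
interviewed at age 14 serve in the 0–4, 5–9 and 10–14 age groups.  Because
one control can appear in several periods, a clustered sandwich variance
(clusters = subjects) is reported alongside the model-based one.  A
no-reuse variant (each control allocated to a single eligible period by
seeded balanced assignment) is included for comparison.

**2. Case-cohort analysis.**  When cases are rare, the controls are
approximately a random sample of the population at risk, so the study can be
analysed as a case-cohort design with the controls as subcohort.  Under

```
h(t | x, z) = h_0s(t) exp(β(t)·x + γ'z)
```

the time-varying log hazard ratio `β(t)` — step, linear, or any custom
basis, on the event-time axis `t` or the time-since-exposure axis `u` — is
estimated by maximising the pseudo-partial likelihood: each case is
compared at its event time with the controls still at risk (same stratum if
frequency matched, i.e. stratum-specific baseline hazards `h_0s`).  Cases
enter only their own risk set (controls are event-free by construction);
ties are handled in Breslow's manner; time-varying exposures enter through
each subject's exposure time, `x(t) = 1{exposure_time ≤ t}`.  The correct
standard errors are the grouped sandwich, since the shared subcohort makes
risk-set contributions dependent.

The package also ships the full synthetic study that validates both methods
(`tvcc.simulate`, `tvcc.study`): five birth cohorts over 1984–2012 with
cohort-specific vaccination uptake (60–90%), piecewise-exponential TB
incidence by 5-year age band (13–45 per 100,000 person-years), a vaccine HR
of 0.25 that rises by 35% every 5 years since vaccination (0.25, 0.34,
0.46, 0.62, 0.83), left truncation at 2003, censoring at the end of 2013,
cases capped at age 19, and controls frequency matched to cases within
birth cohorts (~582 cases + as many controls per dataset).

## Worked example

```python
import numpy as np
from tvcc import (SimulationConfig, simulate_case_control, PeriodLogistic,
                  CaseCohort, StepCoefficient, LogisticSpec, DEFAULT_GRID)

subjects, truth = simulate_case_control(SimulationConfig(), seed=42)
truth["n_cases"], truth["n_controls"]        # (608, 608)

spec = LogisticSpec(stratify_intercepts=True,
                    intercept_structure="full_interaction")
res = PeriodLogistic(subjects, DEFAULT_GRID, definition="i", spec=spec).fit()
res.period_log_or.round(3)
# x:[0,5)     -1.461
# x:[5,10)    -1.037
# x:[10,15)   -0.954
# x:[15,20)   -0.272

cc = CaseCohort(subjects, StepCoefficient(DEFAULT_GRID), stratified=True).fit()
cc.to_frame().round(3)
#            estimate  ratio  model_se  robust_se  ci_lower  ci_upper
# x:[0,5)      -1.423  0.241     0.173      0.281    -1.762    -1.084
# x:[5,10)     -0.990  0.371     0.235      0.301    -1.451    -0.529
# x:[10,15)    -0.898  0.407     0.219      0.257    -1.327    -0.469
# x:[15,20)    -0.228  0.796     0.131      0.181    -0.485     0.029
```

Both analyses recover the waning pattern of this dataset's generating
schedule (true log HRs −1.386, −1.079, −0.777, −0.478): protection is
strong in the first five years after vaccination (HR ≈ 0.24) and fades
towards the null by ages 15–19, with single-dataset noise of roughly ±0.2
on the log scale.  `res.summary()` / `cc.summary()` print the full
parameter tables; `cc.beta_at([2, 7, 12])` evaluates the fitted β(t) with
delta-method standard errors; `cc.risk_set_audit` reports the risk-set size
distribution (here 608 risk sets, median 106 members).

The same steps are available from a shell:

```sh
tvcc simulate --seed 42 --out subjects.csv --truth truth.json
tvcc fit-logistic  --data subjects.csv --definition i --out fit_logistic.json
tvcc fit-casecohort --data subjects.csv --coef step --grid 0,5,10,15,20 --out fit_cc.json
tvcc simstudy --reps 200 --seed 1 --out table.csv
```

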
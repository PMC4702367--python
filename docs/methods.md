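# Methods

This note records the statistical models `tvcc` implements, the conventions
chosen where several were defensible, the numerical machinery, and what the
synthetic study does and does not establish.

## Data model

A dataset is one row per subject: case status, entry time `T_E` (the time
from which the subject could have been observed as a case; left truncation),
index time `T_I` (event time for cases; last known event-free time for
controls), binary exposure with an optional exposure (vaccination) time,
covariates `z1..zK` with time-constant effects, and a frequency-matching
stratum.  All times are continuous (fractional years) and are never rounded:
the period-boundary semantics below are exact inequalities on floats.

Time periods are half-open, `[τ_lA, τ_lB)`, with consecutive periods
sharing boundaries.  The boundary convention is ours — the labels "age 0–4 /
5–9" do not decide whether τ itself is in the lower or upper period — but it
is the only convention under which the four eligibility definitions'
deliberate mix of strict and non-strict inequalities (`T_E < τ_lB` vs
`T_E ≤ τ_lA`, `T_I ≥ τ_lA` vs `T_I > τ_lB`) is unambiguous in continuous
time, and it reproduces the canonical example (a control interviewed at 14
on a 5-year grid serves in exactly three age groups).  The eligibility
inequalities are implemented exactly as stated, with no "clean-up": the
contrast between definitions (i)–(iv) is the experimental question, and the
nesting lattice (iv = ii ∧ iii ⊂ i) is asserted by enumeration in the tests.
A control whose index time lies beyond the last boundary is eligible
wherever the inequalities say it is; nothing is truncated.

## Period-wise logistic likelihood

The expanded dataset contains one record per case (in its event period,
`D = 1`) and, with reuse, one `D = 0` record per (control, eligible period)
pair.  The fitted objective is the product of Bernoulli terms over emitted
records — the full likelihood of the period model restricted to the records
that contribute.  Cases never appear as controls in earlier periods: that
would over-represent future cases, and under the rare-disease assumption the
slight *under*-representation from excluding them is negligible.

Intercept structures for frequency-matched data:

* `period_only` (default for unstratified data): one δ_0l per period.
* `stratum_only`, `additive`, `full_interaction` when stratification is on.

The simulation-study runner uses `full_interaction` (δ_0ls, one intercept
per period-stratum cell), not `additive`.  The reason is empirical and
structural: in this design the stratum composition of the analysis periods
differs sharply (the 0–4 period draws only on recent birth cohorts, the
15–19 period only on early ones), so per-period case/control balance within
a stratum is far from additive in (period, stratum); shared additive
stratum offsets misspecify the per-period intercepts and attenuate the
exposure effects by up to ~0.14 on the log-OR scale in pilot runs.  The
saturated structure is equivalent to fitting each period's
stratum-adjusted model separately and is unbiased here.  Cells containing
only cases or only controls identify their own intercept at ±∞ and carry no
information about the exposure effect; they are dropped before fitting (the
profile-likelihood limit, analogous to discarding concordant strata in
conditional analyses), with a log message.

Exposure-by-period columns use absolute coding (one δ_Xl per period, no
reference level), so each coefficient is directly the period-l log odds
ratio.  Covariate effects are shared across periods by default.

Variances: the model-based variance is the inverse observed information.
Whenever a control contributes more than one record while any parameter is
shared across periods — and by default always — a clustered sandwich is also
computed: bread = inverse information, meat = Σ over subjects of the outer
product of the within-subject summed score, times the small-sample factor
G/(G−1) (G = number of subjects; the standard correction, chosen here as
the smallest conventional one).

## Case-cohort pseudo-partial likelihood

Treating the controls as the subcohort, each case `i_j` at event time `t_j`
contributes

```
exp(η_{i_j}) / Σ_{k ∈ R_j} exp(η_k),   η_k = β(u_kj)·x_k(t_j) + γ'z_k
```

where `R_j` holds the case plus every control with `T_E < t_j ≤ T_I` (and
the case's stratum, when baselines are stratified).  Conventions:

* **At-risk boundary.**  Right-closed: a control interviewed exactly at an
  event time is still at risk there.  The source of the rule ("at risk up
  until their index time") does not fix the endpoint; including it keeps
  the most information and matches the survival convention that a subject
  is at risk at its own event time.
* **Case entry.**  The standard software recipe moves each case's entry to
  "an instant before" its event (an ε perturbation).  Here the rule is
  structural: case rows are simply never members of other risk sets, so no
  floating-point ε exists and exact ties cannot interact with it.  The
  option `include_case_followup=True` restores case rows to the at-risk
  pool over `(T_E, T_I]` — the situation of a subcohort that contains the
  cases — and in that mode the fit coincides with an ordinary Cox
  partial-likelihood fit with left truncation, which the tests verify
  against an independent implementation to 1e-6.
* **Ties.**  Breslow only: tied event times yield distinct risk sets with
  identical membership.  Efron weighting is not implemented.
* **Time axes.**  `t` (event time) or `u` (time since exposure); each
  member evaluates the coefficient basis at its own `u_kj = t_j −
  exposure_time_k`, and a member not yet exposed at `t_j` has
  `x_k(t_j) = 0`, so β(u) is never evaluated at negative u.  The default is
  `u` when exposure times vary among exposed subjects and `t` otherwise
  (with exposure at time 0 the two coincide).
* **Coefficient models.**  Constant, step on a period grid, linear
  `β_0 + β_1 t`, or user-supplied basis functions (the hook through which
  splines can be plugged in; no spline basis is bundled).

The model-based variance (inverse information of the pseudo-partial
likelihood) is known to be anticonservative here: the subcohort is shared
across risk sets, so contributions are positively dependent.  The reported
robust variance is the grouped Lin–Wei/Barlow sandwich: each member's
influence in risk set j is `(δ_kj − π_kj)(φ_kj − φ̄_j)` (score residual
measured against the risk set's weighted mean covariate), summed within
subject, with the G/(G−1) factor.  In the default study configuration the
inverse-information SE understates the sampling SD by ~35% while the
sandwich matches it; consequently the study summary attaches the sandwich
SE to the case-cohort method (see below).

## Numerical machinery

Both objectives are concave and share one Newton–Raphson maximiser:
analytic gradient and Hessian, step-halving (a step is never accepted if it
lowers the objective), convergence when `max|score| < 1e-8` and the
relative objective change is below 1e-10, at most 100 iterations.  The
strict tolerances make equivalence tests against independent
implementations exact rather than approximate.  Per-risk-set
max-subtraction guards the exponentials.

Separation handling: an iterate with any |coefficient| > 15 aborts with a
separation error (on the log-OR/log-HR scale such values only arise when
the maximiser is at infinity), as does quasi-separation in which the score
converges while the likelihood is flat — detected as an eigenvalue ratio of
the observed information above 1e8 at the optimum.  Designs are pre-checked
for the obvious cases (a period with only cases or only controls, no
exposed records in a period) so the error names the offending period.
Degenerate inputs (no cases, no controls, empty grids, times outside the
grid) raise typed errors naming the offending subject or period.

## Synthetic data generator

The generator emulates the motivating vaccine study:

* Five contiguous birth cohorts over [1984, 2012); equal widths by default
  (the source states only the overall span).  Dates of birth uniform within
  cohort.
* Vaccination uptake 60%, 60%, 80%, 90%, 90% by cohort; vaccination at
  birth by default (so age = time since exposure), or at a configurable
  (uniform) age for exercising genuinely time-varying exposures.
* Baseline incidence, per person-year, by 5-year age band:
  {13, 14, 16, 36, 40, 45}×10⁻⁵ (ages beyond 30 keep the last rate — with
  the age-19 case cap those events only feed censoring, but the hazard must
  be total).  Rates are interpreted per person-year, the only reading under
  which a piecewise-exponential hazard is defined.
* Hazard ratio since vaccination: 0.25 rising by 35% every 5 years.  The
  published schedule states, and uses, each band rounded to two decimals
  (0.25, 0.34, 0.46, 0.62, 0.83), and the study's "true log HR" values are
  the logs of the rounded numbers, so `SimulationConfig` rounds each band
  to 2 dp by default (`hr_rounding=None` restores the raw compound rule;
  the difference is below 0.01 on the log scale but is visible as a
  systematic offset in 200-replicate means).
* Event ages are drawn by exact inversion of the piecewise-linear
  cumulative hazard (knots at every 5-year multiple, the rate-band bounds
  and the vaccination-age offsets; the final hazard extends indefinitely so
  the inversion is total).  The sampler is validated against its
  closed-form CDF by a Kolmogorov–Smirnov test at n = 10,000.
* Calendar arithmetic is continuous: events are observable from 2003.0,
  follow-up ends at 2014.0 ("end of 2013"), cases must have event age < 20
  and event date within the window; a person whose event falls outside the
  window or above the cap is excluded from both the cases and the control
  pool.  Controls get `T_E = max(0, 2003 − birth)` and
  `T_I = 2014 − birth`.
* Controls are frequency matched: within each birth cohort, a simple random
  sample of event-free persons of the same size as the cohort's case count.

Cohort sizes are not given by the source; `calibrate_cohort_sizes` scales
them by pilot simulation so the expected total case count hits a target
(default 582) with approximately equal counts per cohort, which supports
the frequency-matched design.  The frozen defaults
(115159, 62823, 110834, 223423, 555243) come from one such calibration run
and give ~1.07M persons per cohort replicate; the late cohorts are large
because incidence under age 8 is low.  Under the defaults the cumulative
incidence to age 20 is below 0.4%, so the rare-disease approximation
(OR ≈ HR, controls ≈ population) holds by a wide margin.

What the generator does **not** emulate: measured covariates `z` (the
study design has none beyond the stratum), non-vaccine secular trends,
waning or heterogeneous vaccination uptake within cohort, imperfect
exposure ascertainment, and competing risks.  Passing tests therefore show
that the estimators recover time-varying effects from correctly specified
rare-event data with clean exposure histories — not that they are robust to
exposure misclassification or confounding.

## Study replication and summaries

`run_study` simulates `n_replicates` independent case-control datasets and
fits six analyses on the 5-year age grid: logistic definitions (i)–(iv)
with reuse, logistic without reuse (controls allocated to one
definition-(i) period each by seeded greedy balancing: visit controls in
random order, assign each to the currently least-filled eligible period,
ties to the earliest), and the stratified case-cohort step model.  Child
seeds derive from `(master seed, replicate index)` so any replicate is
reproducible in isolation; a failing method is recorded with its error and
does not abort the replicate.

The summary computes, per method and age group: exp(mean log estimate),
mean log estimate, mean difference from the generating log HR, empirical SD
(ddof 1), mean standard error, coverage of `estimate ± 1.96·SE` against the
generating log HR, and relative efficiency
`100 · empSD_ref² / empSD_method²` against logistic definition (i).
`se_source` picks the SE feeding the SE and coverage columns: `"model"`,
`"robust"`, or the default `"auto"` — model-based for the logistic methods,
sandwich for the case-cohort method.  `auto` is the statistically coherent
choice (the pseudo-partial likelihood requires the sandwich; the logistic
study fits share no exposure parameters across periods, and their model and
robust SEs agree to two decimals in practice), and it is the only choice
under which all methods' reported SEs track their empirical SDs.

**Problem sizes.**  The package's validation profile is 200 replicates of
the full-size design (the "desk profile"); the published study used 1000,
which `run_study(n_replicates=1000)` reproduces directly.  At 200
replicates the Monte-Carlo uncertainty of a mean log effect is ~0.02, of a
coverage proportion ~0.015, of an empirical SD ~5%, and of a
relative-efficiency ratio ~5–6 points (measured by paired bootstrap over
replicates — variance ratios are noisy, and this is the tolerance scale the
acceptance tests use, with a 10-point floor).  The tests around bias use an
absolute band of 0.04 + 2 MC-SE: the stricter eligibility definitions carry
a real finite-sample attenuation of up to ~0.04 on the log scale (visible
in the published 1000-replicate table as well), which a pure
2-standard-error criterion would flag as replication counts grow.

## Known limitations

* Logistic approach: step-function effects only; time-varying exposures are
  out of scope (use the case-cohort model); no conditional (matched-set)
  logistic engine; no penalised/Firth fallback under separation.
* Case-cohort: Breslow ties only; no baseline-hazard estimation; no
  Barlow/Borgan weighting and no weighted extensions for non-rare outcomes;
  smooth coefficients are limited to what the basis hook expresses.
* The no-reuse allocation is one reasonable reading of "as equal as
  possible"; other balancing schemes would give slightly different
  no-reuse efficiencies.
* Singleton risk sets are retained (they contribute nothing) and only
  reported in the audit.
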
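# Methods

This note records the statistical model, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations of the implementation.

## Relative survival and excess hazard

All modelling is on the excess hazard scale.  With S\*(t) and h\*(t) the
expected survival and hazard of a general-population group matched on age,
sex and calendar year, the patients' all-cause quantities decompose as
S(t) = S\*(t)·R(t) and h(t) = h\*(t) + λ(t).  R(t), the relative survival,
estimates net survival without cause-of-death information; λ(t) is the
mortality attributable to the disease.  Expected rates come from a rate
table indexed by single year of age × calendar year × sex, treated as
piecewise constant within cells; attained age and year are indexed by
completed years (floor) and capped at the table boundaries.  The expected
cumulative hazard H\*(t) is integrated exactly, splitting the integral at
every age- and calendar-year boundary crossing.

## The flexible parametric cure model

The baseline log cumulative excess hazard is a restricted cubic spline in
x = ln t.  Two bases are implemented:

- **standard**: v₁(x) = x and, for j = 2..K−1,
  vⱼ(x) = (x−kⱼ)₊³ − λⱼ(x−k₁)₊³ − (1−λⱼ)(x−k_K)₊³ with
  λⱼ = (k_K−kⱼ)/(k_K−k₁) — linear below the first knot;
- **backward**: the knots are taken in reversed order,
  vⱼ(x) = (k_{K−j+1}−x)₊³ − μⱼ(k_K−x)₊³ − (1−μⱼ)(k₁−x)₊³ with
  μⱼ = (k_{K−j+1}−k₁)/(k_K−k₁) — every non-linear column is exactly zero at
  and beyond the last knot.

The two bases span the same function space (verified by the test suite:
unrestricted fits agree to 1e-6 in log-likelihood and fitted curves), so
the parameterisation is a free choice; other span-equivalent conventions
exist in the literature, and individual coefficient values (not fitted
curves) may differ between implementations.

Cure is imposed structurally, not by constrained optimisation: the backward
basis is built *without* its linear column, so the represented function is
exactly constant on [k_K, ∞) and the fitted excess hazard is identically
zero there — the plateau identities in the tests are exact to the last bit,
not to a tolerance.

Spline columns are Gram–Schmidt orthogonalised against a constant (a QR
factorisation with a recorded upper-triangular transform, replayed exactly
at prediction time) for numerical conditioning, and then centered on their
value at the last knot.  Centering restores the direct cure interpretation
that orthogonalisation would otherwise destroy: the intercept is the log
cumulative excess hazard at and beyond the last knot, so
π = exp(−exp(γ₀₀ + zᵀβ)) for any covariate pattern, exactly.  Centering is
applied in all flexible fits (also unrestricted ones), so intercepts are
comparable between restricted and unrestricted models.

Time-dependent effects interact covariate columns with their own spline
(default knots at centiles 0/25/50/75/100 of log death times — fewer than
the baseline, which is usually sufficient).  Under the cure restriction the
linear term is removed from every time-dependent spline as well; all
time-dependent columns then vanish beyond the last knot, so cure still
depends only on the constant parameters.  All time-dependent effects share
one knot vector; per-effect knot vectors were not needed for any analysis
here and are a possible extension.

## Likelihood and optimisation

The model is fitted by maximum likelihood on individual data.  On the log
cumulative excess hazard scale, Λ(t) = exp(η(x)) and, by the chain rule,
λ(t) = Λ(t)·(dη/dx)/t, so each subject contributes

  ℓᵢ = dᵢ · ln( h\*ᵢ(tᵢ) + λ(tᵢ) ) − Λ(tᵢ),

the parameter-free ln S\*(tᵢ) term being dropped.  Because the spline slope
is unconstrained, λ can go negative during optimisation, making the log
undefined when h\* + λ ≤ 0.  Below a threshold ε = 1e-8 the log is continued
linearly (value and first derivative matched at ε), which acts as a smooth,
steep penalty; any *event* record still sitting in that region at the MLE is
reported with a warning, and the count of records with negative fitted
excess hazard is stored on the fit (`n_negative_excess_`).  Small negative
fitted excess hazards among censored records just before the plateau are
common and benign — they show up as a fitted R(t) that rises by O(1e-4)
before flattening.

Optimisation minimises the *mean* negative log-likelihood (per-subject
scale, which makes tolerances independent of n) by BFGS with the analytic
gradient, followed by Newton polishing steps using a central-difference
Hessian of the analytic gradient.  Convergence is declared when the
max-norm of the mean-scale gradient is below 1e-5; if after up to three
perturbed restarts the gradient max-norm still exceeds 1e-3 the fit raises
a `ConvergenceError` carrying the iteration trace.  Starting values come
from a least-squares fit of the design to the log cumulative hazard of a
constant-excess-rate (exponential) model.  Standard errors are the inverse
of the central-difference observed information at the MLE.  The Weibull
mixture and non-mixture models use the same machinery with
finite-difference gradients (three to nine parameters; π linked log(−log),
scale and shape linked log).

Records with t = 0 (same-day deaths) are shifted to half the smallest
positive follow-up time and counted on the fit; delayed entry is not
supported.

## Predictions and confidence intervals

- π: delta method on the log(−log) scale — exact, since γ₀₀ + zᵀβ is linear
  in the parameters; intervals respect (0, 1).
- R(t): delta method on the ln Λ scale (exact for flexible models,
  finite-difference parameter gradients for Weibull families).
- S_u(t) = (R − π)/(1 − π): delta method on the plain scale, clipped to
  [0, 1].
- median of the uncured: Newton–Raphson on ln t for S_u(t) = ½ (bisection
  fallback bracketed at the cure point), with the delta-method interval on
  the log-time scale via the implicit-function derivative.  The log-time
  scale keeps the interval positive; whether to put the interval on t or
  ln t is a genuine open choice and ln t was chosen.  If S_u is still above
  ½ at the cure point a `MedianNotReached` error is raised — impossible for
  a converged flexible cure fit (S_u reaches 0 at the last knot by
  construction) but reachable for degenerate Weibull parameter values.

Predicting cure requires the last knot at or beyond the last death time;
the fitter warns when a knot rule violates this.

## Ederer II life tables

Interval-based actuarial estimation: observed conditional survival
pᵢ = 1 − dᵢ/(nᵢ − cᵢ/2) (half-interval censoring adjustment); expected
conditional survival p\*ᵢ is the mean over patients at risk at the interval
start of exp(−ΔH\*) across the interval — the expectation follows only
those still at risk, which is what distinguishes Ederer II.  Cumulative
relative survival is Π(pᵢ/p\*ᵢ) with a Greenwood variance on the observed
component (the expected component is treated as fixed).  The default
interval grid is monthly over the first year and annual thereafter,
capturing the early period where the excess hazard is largest; the grid is
a configuration choice.

## The synthetic-data generator

The generator emulates a registry cohort of the kind the method targets: a
cured fraction experiencing only background mortality, an uncured fraction
with parametric excess event times, covariates (age group, calendar period,
sex), and administrative censoring 10 years after diagnosis.  Background
death times are drawn by inverting each subject's expected cumulative
hazard under the same rate-table machinery the likelihood uses, so
generator and estimator are internally consistent by construction.
Synthetic rate tables are log-linear in age (default slope 0.09 per year,
about a doubling every 8 years, intercept −10 — roughly 1.6% annual
mortality at age 65), with a small sex contrast.  Latent cure status is
stored only in the truth record: statistical cure is a population property,
and the analysis-facing files never contain it.

Packaged scenarios (defaults chosen once, as registry-realistic anchors):

- `recovery_scenario(pi)`: one covariate pattern, ages 55–75, Weibull
  survival of the uncured with shape 1.1 and median 0.645 y — used for
  parameter-recovery studies at π ∈ {0.3, 0.5, 0.8} and n = 5000.
- `oldage_scenario()`: ages 80–90 (high background mortality), π = 0.40,
  and a two-component Weibull survival of the uncured (65% with
  characteristic life 0.15 y, shape 0.8; 35% with 2.5 y, shape 1.1).  The
  true excess hazard at 0.1 y is ~11× its value at 1 y, over half the
  uncured die within 3 months, and the true median survival of the uncured
  is ~0.21 y — the sharp early spike typical of the oldest age groups that
  a single-Weibull cure model cannot track.
- `highcure_scenario()`: π = 0.85, n = 2000 — the localised-disease regime
  where classical cure models often fail to converge.
- `default_scenario()`: 5 age groups × 5 calendar periods with cure
  decreasing in age, for workflow-level demonstrations.

What the generator does **not** emulate: period effects on background
mortality interacting with follow-up, informative or emigration censoring,
delayed entry, multi-state relapse structure, or covariate-dependent
survival of the uncured within a scenario cell.  Passing recovery tests on
these cohorts therefore shows the estimator is correct under its own
assumptions and robust to the specific misspecifications studied (sharp
early hazards, high cure); it does not certify behaviour under data
features the generator omits.

## Knot placement

Knot rules are strings over centiles of log observed death times, optionally
with a pinned late knot (e.g. `"centiles 0 25 50 75 95 + fixed 12"`, the
default: a 6-knot rule with the last knot at 12 years, outside 10-year
follow-up, so no cure point is imposed inside the data).  The six rules of
the sensitivity protocol are packaged as `SENSITIVITY_KNOT_RULES`; on a
simulated cohort the cure estimates of the rules whose last knot is at or
beyond the last death time agree within about one percentage point.

Because most death times occur early in follow-up, centile-based rules
crowd knots into the first year.  For shapes with a very sharp early excess
hazard this leaves the plateau under-supported and biases the cure
proportion slightly upward — measured at +0.4pp for early-heavy 8–9-knot
rules on the old-age scenario (150 replicates, n = 3000) and −0.7pp for the
default 6-knot rule, versus +0.0pp for the late-spread rule
`"centiles 0 35 65 80 95 + fixed 12"` (packaged as `OLDAGE_KNOT_RULE`).
The practical rule: spread knots over the whole follow-up and put the last
knot at or after the last death time.

## Problem sizes used in validation

The acceptance workflow uses 99 cohorts of n = 5000 for recovery (33 per
cure level), 50 replicates of n = 3000 for the old-age bias contrast, 50
replicates of n = 2000 for high-cure convergence, n = 20000 for life-table
and knot-sensitivity checks, and 1000 random points for the spline oracles;
these sizes give Monte-Carlo standard errors of ~0.2pp on bias estimates
while keeping the full run around half a minute on one core.

## Known limitations

- No delayed entry / left truncation; no period-analysis weighting.
- Ederer I and Hakulinen expected-survival estimators are out of scope.
- The likelihood treats the rate table as known, as is standard.
- CIs for S_u are on the plain scale and can touch the boundary for
  patterns with π near 1.
- The cure LRT compares fit over the whole time scale; as the CLI report
  notes, graphical assessment against life-table estimates is the
  recommended way to judge the cure assumption.
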
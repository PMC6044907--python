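# Methods

## Model

`iced` fits a parallel measurement model with orthogonal variance
components to person-by-occasion data. For person *p* at occasion *o*:

    y_po = μ + T_p + Σ_f u_{f, level_f(o)}^{(p)} + e_po

* **T_p ~ N(0, σ²_T)** — the person's true score; its variance is the
  between-person variance of the construct.
* **u^{(p)}_{f,l} ~ N(0, σ²_f)** — one random effect per facet level
  (e.g. a fresh day effect per day, a fresh session effect per
  session), drawn independently per person. Facet effects are
  person-level nuisances, not calendar effects shared across persons.
  Every level of a facet shares the single variance σ²_f.
* **e_po ~ N(0, σ²_E)** — residual error, independent across occasions.

All loadings are fixed at 1 and residual variances are equal across
occasions (the parallel-model assumption: the construct is measured on
the same scale with the same precision at each occasion). The implied
covariance is Σ = σ²_T J + Σ_f σ²_f Z_f Z_f' + σ²_E I, with Z_f the
occasion-by-level indicator; off-diagonal entries accumulate exactly
the variances of the components two occasions share. Facets may be
nested (sessions within days) or crossed (scanner × day): nesting is
implied by the membership map, never declared, and not enforced.

The mean structure is a single common mean μ by default; per-occasion
means are available (`per_occasion_means=True`) but off by default,
since the parallel model presumes a common scale.

## Identifiability

A design identifies its components iff the Jacobian of the unique
covariance entries (upper triangle) with respect to
(σ²_T, σ²_f …, σ²_E) has full column rank. Σ is linear in the
variances, so the Jacobian is constant; the check nevertheless follows
the generic numerical recipe — central differences at three random
strictly positive points drawn uniform(0.5, 2.0) from a fixed seed
(20180702), rank from singular values at relative tolerance 1e-8 —
because it extends unchanged to future nonlinear structures and
multiple points guard against accidental degeneracy. Confounded
parameter sets are read off the null-space vectors: parameters with
non-zero support in a common null vector are inseparable. Two canonical
failures: a facet with a single level covering all occasions is
confounded with the true score, and a two-occasion design cannot
separate a two-level session facet from the residual.

## Estimation

Full-information maximum likelihood: each person contributes the
multivariate-normal log-density of their observed cells under the
matching submatrix of Σ, which is valid under missing-at-random.
Persons are grouped by missingness pattern (one Cholesky per pattern
per likelihood evaluation), and rows are internally sorted by person id
so that results are bit-for-bit invariant to the input row order.

Optimisation is box-constrained L-BFGS-B over (μ, variances) with
lower bound 0 on every variance, so maximum-likelihood estimates cannot
go negative; estimates landing at 0 (≤ 1e-8) are boundary-flagged.
Starting values come from method-of-moments (grand mean; between-person
variance of person means corrected by the mean within-person variance;
within-person variance split equally over error components), plus by
default 5 random restarts with multiplicative log-normal perturbations;
the best converged optimum is kept. Convergence tolerance is 1e-10 on
the scaled objective. Non-PD covariance proposals receive a large
finite penalty rather than −∞, keeping the optimiser stable near the
boundary.

Standard errors come from the inverse observed information, computed by
central-difference Hessian at the optimum. At a zero bound the
curvature is one-sided and the Wald approximation fails; SEs of
boundary-flagged parameters are reported as NaN.

## Inference conventions

* **LRT of a component = 0**: refit with the component fixed at zero;
  −2Δℓ referred to χ²(1). The null lies on the boundary of the
  parameter space, so this reference is conservative (type-I error
  below nominal); the statistically preferable 50:50 χ²(0):χ²(1)
  mixture is available via `mixture=True` and exactly halves the
  p-value for positive statistics.
* **Residual component**: its null model (no orthogonal residual
  structure) has a singular covariance for any within-session pair and
  cannot be estimated; requesting that LRT raises an error pointing to
  the Wald test.
* **Wald test**: W = (estimate/SE)² on χ²(1). Reporting the squared
  statistic keeps one consistent reference distribution for all tests.
* **Equality of two components**: a 1-df constrained refit in which the
  two components share one free variance (an interior null; plain
  χ²(1) applies).
* **Multi-group models**: the joint likelihood is the sum over groups;
  components named in `equal=[...]` (and optionally `mu`) share one
  value across groups. Testing cross-group equality of an error
  component — e.g. the session component across mirrored designs with
  the repositioning on different days — is a session-by-day interaction
  test: `interaction_lrt(free, constrained)` with df equal to the
  number of constraints. A constrained likelihood exceeding the free
  one beyond tolerance (1e-4 relative) raises, since it can only signal
  optimiser failure.

## Effective error and ICC2

The effective error is implemented as the generalized-least-squares
precision of the unit-loading latent factor,

    σ²_eff = 1 / (1' Σ_E⁻¹ 1),

with Σ_E the model-implied covariance of the error part alone. This
choice is validated two ways: it reproduces the classical σ²_E/n limit
exactly when all facet variances vanish (checked for n = 2…10), and it
matches the analytic closed form (σ²_E+σ²_S)(σ²_E+2σ²_S)/(3σ²_E+4σ²_S)
for the three-scan design to 1e-10 over randomized components. For the
two-day four-scan design a closed form sometimes quoted for this
layout, (2σ²_D+σ²_E+σ²_S)(2σ²_D+σ²_E+2σ²_S)/(8σ²_D+4σ²_E+3σ²_S),
agrees with the GLS value only when σ²_S = 0; the GLS derivation gives
denominator 8σ²_D+4σ²_E+**6**σ²_S (at all components 1: 10/9 versus
4/3). We treat the 3-coefficient version as a transcription error and
use the GLS route throughout; a unit test documents the discrepancy.

ICC2 = σ²_T/(σ²_T + σ²_eff) is construct-level reliability. Because
σ²_eff can never exceed the total error variance of a single occasion,
ICC2 ≥ ICC always. D-study curves (`reliability_curve`, `iced dstudy`)
evaluate ICC2 over a family of designs; adding runs averages out the
residual but not the session/day components, so curves asymptote
strictly below 1 whenever a facet variance is positive — the asymptote
is the ICC2 of the session-level design with the session variance as
residual.

Display rounding is two decimals for ICC/ICC2 in text reports, matching
common reporting practice; JSON reports keep full double precision.

## Synthetic data

The generator draws data exactly under the model above, so it emulates:
(a) the three-scan single-day layout with a repositioned third scan;
(b) the minimal two-day, three-session, four-scan layout identifying
day + session + residual; and (c) the joint
longitudinal + cross-sectional layout, where a small deeply-measured
sample (default emulation: 8 persons × 10 occasions) is stacked with a
larger single-occasion sample under an exactly mutually exclusive
missingness pattern — cross-sectional persons are observed on one fresh
occasion only, sharpening σ²_T while the longitudinal arm pins down the
within-person components.

What the generator does **not** emulate, and hence what passing tests
do not show about real data: true-score change over time (growth),
autocorrelated or heteroscedastic residuals, non-Gaussian effects,
occasion-specific loadings, informative missingness, and calendar
effects shared across persons. The aggregated coefficient of variation
(`aggregated_cv` — square root of the mean within-person variance over
the grand mean) is provided to demonstrate that CV-indexed precision is
invariant to between-person heterogeneity while the ICC is not; the
demonstration fixes person means near 10× the within-person SD so the
grand mean is far from zero, an illustrative choice since the CV is
meaningless near zero.

## Problem sizes and numerical choices in the test-suite

Monte-Carlo checks use sizes chosen to make their claims statistically
comfortable: parameter recovery at 500 persons × 200 replicates
(|relative bias| < 5% for all components; 95% Wald coverage within
[90%, 98%] for interior parameters), type-I error of the session LRT at
200 persons × 2000 replicates (empirical rejection ≤ 0.05 + 2 MC-SE,
conservative under the boundary null), and a law-of-large-numbers check
of the generator at 100 000 persons (sample covariance within 2%
entrywise). Simulation fits use a single restart — the
method-of-moments start is reliable at these sizes — while interactive
fits default to 5.

## Known limitations

* Only the parallel model: no congeneric/tau-equivalent loadings or
  occasion-specific residual variances.
* REML, Bayesian inference and robust (sandwich) standard errors are
  not provided; likelihood-based SEs assume correct model and
  normality.
* Level-specific facet variances (e.g. a different variance per day)
  are not supported — one variance per facet.
* Reliability of *change* (growth-curve extensions) is out of scope;
  the model assumes a stable true score over occasions, so long
  measurement spans with real change will deflate the ICC toward a
  stability coefficient.
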
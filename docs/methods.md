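# Methods

`jointbone` analyses cohorts in which a strictly positive bone-turnover
biomarker (such as urinary NTX, in nmol BCE/mmol creatinine) is measured on a
sparse visit grid while patients are followed to death or censoring. Its core
is a shared-parameter joint model linking the biomarker trajectory to the
hazard, surrounded by the supporting machinery a full analysis needs:
simulation with known truth, missing-data handling, mixed-effects trajectory
fits, and classical survival regression.

## Models

**Longitudinal sub-model.** The log biomarker of patient *i* is

    y_i(t) = m_i(t) + eps_i(t),      m_i(t) = x(t)'(beta + b_i),
    b_i ~ N(0, D),  eps ~ N(0, sigma^2),

with the random-effects design equal to the fixed-effects design (z = x):
every patient deviates randomly from every population coefficient. Working on
the log scale keeps the right-skewed raw values approximately Gaussian and
makes the association parameter interpretable per log-unit. Three mean
families are available:

* rational: `x(t) = (1, (t + delta)^-eta)`, `delta, eta > 0`;
* exponential: `x(t) = (1, exp(-delta t))`, `delta > 0`;
* natural cubic spline with k = 2 interior knots (basis dimension 4), built
  from truncated cubes with the natural constraints (linear beyond the
  boundary knots). Interior knots default to the 33rd/67th percentiles of the
  observed measurement times — months 1 and 6 under the default visit grid —
  and boundary knots to the observed extremes.

The decay tuning parameters are not estimated inside the linear fit; they are
profiled: the marginal ML log-likelihood is maximized over a log-spaced grid
on [1e-2, 1e2] (25 points for the one-parameter exponential family; 5 per
axis for the two-parameter rational family, whose profile surface is a flat
ridge that a dense grid would oversample) followed by a bounded Nelder–Mead
refinement. Each grid point is fit from a neutral start; warm-starting across
tuning values was found to hand poor local optima to the comparison. A flat
profile (spread under 2 log-likelihood units across the grid) is reported as
a boundary fit with `delta` at the lower bound: the data carry no decay
signal and the tuning is unidentified.

**Survival sub-model.** The hazard is

    h_i(t | b_i) = h0(t) exp{gamma' w_i + alpha m_i(t)},

with baseline covariates `w_i` (age at diagnosis in years, sex, extra-bone
metastases), a piecewise-constant baseline hazard `h0`, and the *current
true value* association `alpha` (no slope or cumulative parameterizations).
Baseline-hazard breaks default to observed event-time sextiles (six pieces,
equal event counts per piece); beyond the last break the final height is
extrapolated.

**Joint likelihood.** Per patient the random effects are integrated out of
longitudinal density x event/survival term x prior. The outer integral uses
adaptive Gauss–Hermite quadrature: a damped Newton search locates the
per-patient posterior mode and curvature, and the Hermite grid is re-centred
and re-scaled there on every likelihood evaluation (9 nodes per dimension for
1–2 random effects, 5 for 3–4; the spline family has 4). The inner cumulative
hazard integral uses 15-point Gauss–Legendre per hazard piece — exact enough
that, when the association is severed (alpha = 0), the joint likelihood
factorizes into the LME marginal and a piecewise-exponential survival
likelihood to 1e-8, which the tests assert.

Maximization is direct quasi-Newton (L-BFGS with an analytic gradient from
the posterior-expectation identity dlogL/dtheta = E[dlog g/dtheta | data])
on unconstrained parameters: the Cholesky factor of D with log diagonal, log
sigma, log hazard heights. EM is not implemented; with the analytic gradient
the direct maximization converges in ~10 iterations from the two-stage
starting values (separate LME fit, Cox fit plus occurrence/exposure heights,
alpha = 0). Internally the covariates are centred and scaled and the
biomarker is centred inside the hazard so the optimizer sees comparably
curved directions; estimates, SEs and hazard heights are mapped back to the
natural scale (height SEs refer to the internal parameterization and are not
reported). Standard errors come from a central-difference Hessian of the
analytic gradient (step 1e-4 on the transformed scale); Wald tests are
two-sided normal with significance labelled at 5%. Convergence is declared
at relative log-likelihood change below 1e-7 (max 200 iterations); a
singular Hessian leaves SEs unavailable rather than fabricated.

Patients with no longitudinal record (possible under the omit strategy)
still contribute: their survival term is integrated over the random-effects
prior.

**Extended Cox comparison.** The classical alternative treats the observed
biomarker as a step function with jumps at the measurement times. The
counting-process builder emits (start, stop] rows — risk at t iff
start < t <= stop — with each interval carrying the last measurement at or
before its start; patients whose first measurement postdates time zero enter
the risk set late, and consecutive intervals with identical covariate values
are merged. The merge makes the omit and LOCF versions of a cohort produce
*identical* row sets, so their extended Cox fits agree exactly — carrying a
last observation forward cannot change a step function built from last
observations. Estimation (and Kaplan–Meier, log-rank, plain Cox) is
delegated to lifelines, which uses Efron's tie correction; the tests pin
these against hand product-limit/hypergeometric computations and dense
grid searches of the partial likelihood.

Because the step function carries measurement error and is frozen between
visits, the extended Cox association is attenuated toward zero relative to
the joint model's alpha — the package's simulation studies reproduce this
ordering and it is asserted in the test suite.

## Missing data

Three strategies, applied to the patients-by-visits matrix:

* **omit** — analyze observed entries only (valid input for both the mixed
  models and the counting-process builder);
* **LOCF** — forward fill along the grid; entries before a patient's first
  observation stay missing;
* **OCS** — fuzzy short-time-series clustering with optimal completion.

FSTS is fuzzy c-means (default c = 6 clusters, fuzzifier m = 1.3) under a
distance on segment slopes: series are read as piecewise-linear functions
and compared through d² = Σ (slope difference)² — a Euclidean distance on
slope vectors, invariant to vertical shifts. Consequences handled
explicitly:

* the prototype system is rank-deficient by one; prototypes are
  level-anchored so their membership-weighted mean level equals that of
  their member series, keeping centroids on the data's scale;
* zero distances get a crisp assignment to the first matching cluster;
* initialization is a deterministic, order-invariant farthest-point scheme
  on slope vectors (first seed = largest slope norm, lexicographic
  tie-breaks), so permuting patients permutes the output identically.

Under OCS the missing cells are free variables of the clustering objective.
Each cycle runs membership update, prototype update, then an *exact*
minimization of the objective over the missing coordinates (a small linear
solve per row — every coordinate enters at least one slope segment and at
least one entry is pinned, so the quadratic is strictly convex). Because
every step is a coordinate-wise minimization the objective is non-increasing
across cycles, which is property-tested. Convergence at max change < 1e-6,
cap 500 iterations.

## Synthetic cohorts

The generator draws from the joint model itself, so every estimator can be
checked against known parameters. Defaults emulate a mixed bone-metastatic
cohort of 147 patients: measurements at months 0, 1, 3, 6, 9, 12; age ~
N(60, 11²), 25% male, 50% extra-bone metastases; log-biomarker decaying
exponentially from log 100 toward log 40 (beta = (3.7, 0.9), delta = 0.5)
with D = [[0.45, -0.05], [-0.05, 0.20]] and sigma = 0.40; survival
coefficients gamma = (0.018, 0.30, 0.66) and alpha = 0.2 on the log scale;
flat baseline hazard 0.006/month; administrative censoring at 30 months
(~70% events). Event times come from inverse-transform sampling: the
cumulative hazard is computed by 15-point Gauss–Legendre per hazard piece —
an independent code path from the estimator's quadrature, so the two check
each other — and inverted by bisection to 1e-10 months on a horizon of
10 x censoring time; patients whose cumulative hazard never reaches the
target are censored.

Missingness is monotone dropout (each post-baseline visit independently
triggers loss of that visit and all later ones, default 15%/visit) plus 5%
intermittent MCAR; the baseline visit is never removed. Combined with death
truncation this reproduces the attrition profile of a real bone-metastasis
cohort (retention roughly 1.0 → 0.75 → 0.56 → 0.40 → 0.28 → 0.22 across the
grid). What the generator does **not** emulate: outcome-dependent
(informative) missingness, multiple primary-cancer strata with different
trajectory shapes, competing risks, and measurement-schedule jitter. Tests
passing on these cohorts therefore demonstrate internal correctness of the
estimators under the model's own assumptions, not robustness to violations
of them.

## Numerical choices and edge cases

* Tolerances: LME optimizer gtol 1e-7 on the profiled likelihood gradient;
  joint model relative-loglik 1e-7; bisection 1e-10 months; FSTS/OCS 1e-6.
* Degenerate inputs: all-identical series with c > 1 are flagged, not
  crashed; a trajectory row must keep at least one observed entry; a
  threshold feature collapsing to one level is skipped and logged by the
  univariate screen; grid-cell failures in the pipeline are isolated and
  recorded while the remaining cells run.
* Determinism: one integer seed fixes cohort simulation end to end;
  clustering is deterministic by construction; re-running the pipeline with
  the same configuration reproduces the result bundle bit for bit, and the
  bundle records a configuration hash.

## Validation studies and problem sizes

`jointbone.validation` packages the simulation studies used by the test
suite and the reproduction script: dense-grid oracle agreement for the joint
likelihood (<= 3 patients, 1–2 random effects); parameter recovery at
n = 300 (3-SE coverage per parameter across seeds); Wald-test size for the
association under alpha = 0 at n = 200; the extended-Cox-vs-joint-model
attenuation comparison under inflated measurement error (sigma = 0.6); and
OCS-vs-LOCF mask-and-recover at 20% missingness. The reproduction script
runs reduced replicate counts (5 recovery seeds, 100 null replicates, 25
attenuation replicates) chosen as the package's own compromise between
Monte-Carlo error and turnaround; the test suite runs the full sizes.

## Known limitations

* One longitudinal outcome; no slope/cumulative association, stratified
  hazards, frailties, competing risks, or dynamic prediction.
* The piecewise-constant baseline hazard is the only baseline family
  (no Weibull/B-spline alternatives).
* Variance-parameter SEs are reported on the transformed scale only; no
  profile-likelihood intervals.
* The rational family's (delta, eta) profile is a flat ridge; the selected
  pair is well-defined but individual values should not be
  over-interpreted.
* Estimation is frequentist ML throughout; no Bayesian machinery.
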
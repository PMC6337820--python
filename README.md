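# jointbone

Joint modelling of bone-turnover biomarker trajectories and survival in
bone-metastatic cancer cohorts.

In follow-up studies of patients with bone metastases, a resorption marker
such as urinary NTX (N-telopeptide of type I collagen, nmol BCE/mmol
creatinine) is measured on a sparse visit grid — here months 0, 1, 3, 6, 9,
12 — while patients are followed until death or censoring. Static snapshots
of the marker (its value at month 3 or 12, or a high/low dichotomy) discard
most of the trajectory; treating the series as a step-function covariate in
an extended Cox model ignores measurement error and biases the association
toward zero. `jointbone` is for biostatisticians who want the full
comparison on such cohorts: classical Cox screens, extended Cox with
time-varying covariates, and a shared-parameter joint model, under three
missing-data strategies.

## The model

Longitudinal sub-model (log scale, random effects sharing the fixed-effects
design, z = x):

    y_i(t) = m_i(t) + eps_i(t),   m_i(t) = x(t)'(beta + b_i),
    b_i ~ N(0, D),                eps ~ N(0, sigma^2)

with `x(t)` one of `(1, (t+delta)^-eta)`, `(1, exp(-delta t))`, or a natural
cubic spline with two interior knots. Survival sub-model with a
piecewise-constant baseline hazard:

    h_i(t | b_i) = h0(t) exp{gamma' w_i + alpha * m_i(t)}

The association `alpha` couples the hazard to the *current true* biomarker
level. The marginal likelihood integrates the shared random effects out by
adaptive Gauss–Hermite quadrature and is maximized by quasi-Newton with an
analytic gradient; the extended Cox alternative runs on (start, stop]
counting-process rows. Missing visits are handled by omission, last
observation carried forward (LOCF), or fuzzy short-time-series clustering
with optimal completion (FSTS + OCS, c = 6 clusters, fuzzifier m = 1.3),
which clusters patients by the slopes of their piecewise-linear series and
imputes missing cells as free variables of the clustering objective.

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

```python
from jointbone import (
    AnalysisConfig, CohortConfig, CohortDataset,
    run_analysis_grid, simulate_cohort,
)

cohort = simulate_cohort(CohortConfig(seed=7))          # 147 patients
data = CohortDataset(baseline=cohort.baseline, longitudinal=cohort.longitudinal)
bundle = run_analysis_grid(data, AnalysisConfig(seed=7))

print(bundle.provenance["n_jm_fits"], bundle.provenance["n_extended_cox_fits"])
jm = bundle.jm
print(jm[(jm.model == 2) & (jm.parameter.isin(["age", "extra_mets", "alpha"]))][
    ["model", "imputation", "basis", "parameter", "estimate", "se", "p"]
].to_string(index=False))
```

prints

```
9 3
 model imputation       basis  parameter  estimate       se        p
     2       omit exponential        age  0.037429 0.010426 0.000331
     2       omit exponential extra_mets  0.686917 0.212743 0.001243
     2       omit exponential      alpha  0.412216 0.184372 0.025366
```

Nine joint models (3 imputation strategies x 3 trajectory families) and
three extended Cox fits were produced. For model 2 (omit + exponential
trajectory): each extra year of age at diagnosis multiplies the hazard by
exp(0.037) ≈ 1.04, extra-bone metastases by exp(0.69) ≈ 1.99, and each
unit of current log-NTX by exp(0.41) ≈ 1.51, all significant at the 5%
Wald level — the cohort was simulated with a positive biomarker-hazard
association (alpha = 0.2, here estimated 0.41 ± 0.18 on 147 patients), and
the joint model flags it.

The same pipeline runs from the shell:

```bash
jointbone simulate --out cohort/ --seed 7
jointbone run --baseline cohort/baseline.csv --longitudinal cohort/longitudinal.csv --out results/ --seed 7
jointbone impute --method ocs --clusters 6 --fuzzifier 1.3 --seed 0 wide.csv imputed.csv
```

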
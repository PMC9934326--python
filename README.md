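# bpjoint

Bayesian joint modelling of bivariate longitudinal blood pressure and
time to first remission of hypertension.

## The problem

In hypertension follow-up cohorts, systolic and diastolic blood pressure
(SBP/DBP, mmHg) are measured repeatedly while patients are followed until
*first remission* — the first attainment of controlled pressure
(SBP < 140 and DBP < 90 mmHg). Modelling the pressure trajectories and the
remission time separately throws away the information that the hazard of
remitting depends on where a patient's true (noise-free) pressures
currently are and how fast they are falling. `bpjoint` implements the
shared-parameter joint model that links the two:

**Longitudinal sub-model** — a bivariate linear mixed model,

```
Y_ij(t) = m_i(t) + eps_ij,          eps_ij ~ N(0, sigma_eps^2)
m_i(t)  = X_i(t)' beta + Z_i(t)' b_i + u_i' delta,   b_i ~ N(0, Sigma)
```

with X(t) = Z(t) = (1, t), correlated random intercepts/slopes
b_i = (a_i1, b_i1, a_i2, b_i2) shared across the two markers, and
time-invariant baseline covariates u_i (demographics, comorbidities, labs,
treatment).

**Survival sub-model** — proportional hazards with a
*current value and slope* association,

```
h_i(t) = h0(t) exp[ gamma' u_i + rho . (m1(t), m1'(t), m2(t), m2'(t)) ]
```

where h0 is piecewise constant and exp(rho_s) is the hazard ratio for a
one-unit increase in the corresponding marker feature. The association
vector carries a global–local ridge shrinkage prior
rho_s ~ N(0, tau psi_s), tau^-1 ~ Gamma(0.1, 0.1),
psi_s^-1 ~ Gamma(1, 0.01); regression coefficients have N(0, 1000) priors.
Inference is full MCMC (Metropolis-within-Gibbs with conjugate blocks; see
`docs/methods.md`).

The package also ships the surrounding analysis layer: a synthetic cohort
generator with exactly this statistical structure (so everything is
testable without patient data), Kaplan–Meier/log-rank descriptives,
baseline-by-outcome contingency tables with chi-square tests, a survival
sample-size formula, hazard-ratio transforms, dynamic prediction of
conditional remission-free probability, and DIC/WAIC model-fit criteria.
It is aimed at biostatisticians studying longitudinal–survival dynamics in
treatment cohorts.

## Worked example

```python
import bpjoint as bj

cohort, lng, surv, truth = bj.generate_cohort(bj.CohortConfig(n_subjects=301, seed=42))
km = bj.km_estimate(surv.time_months, surv.event)
res = bj.chi_square_association([[30, 53], [28, 190]])   # diabetes x outcome counts
_, corr0 = bj.marginal_covariance(truth.lmm, 0)
hr = bj.hazard_ratio_summary(-0.1128)
```

prints, with the values the code actually produces:

```
subjects: 301, visits: 4434, events: 244 (81.1%)
KM median remission time: 11.5 months
DM x outcome chi-square: 19.509 (p=1.00e-05)
marginal SBP-DBP correlation at t=0: 0.2603
marginal SBP-DBP correlation at t=1: 0.2468
HR per mmHg SBP: 0.8933 (10.67% decrease)
required n (alpha=.05, power=.80, p=.504, logHR=.4121): 367
```

The default generator reproduces a cohort like the source study's: about
81% of 301 subjects remit within the 30-month window with a median
remission time near 11 months; a history of diabetes is strongly
associated with remaining uncontrolled (chi-square 19.5); the shared
random effects imply a marginal SBP–DBP correlation of about 0.26 at
enrolment; and an association coefficient of −0.1128 means each extra
mmHg of true SBP lowers the remission rate by 10.67% (HR 0.89).

Fitting the model to a generated cohort and recovering its parameters:

```python
chains = bj.run_mcmc(cohort, lng, surv,
                     bj.MCMCConfig(n_chains=2, n_iter=4000, burn_in=2000, thin=5, seed=11))
chains.summary()          # post mean / SE / 95% CI / R-hat / ESS per parameter
bj.model_fit_criteria(chains)   # DIC and WAIC
```

The same pipeline is scriptable from a shell:

```bash
bpjoint simulate --seed 42 --out sim/
bpjoint describe --baseline sim/baseline.csv --surv sim/survival.csv --out table.csv
bpjoint fit --long sim/longitudinal.csv --surv sim/survival.csv \
            --baseline sim/baseline.csv --seed 11 --out fit/
bpjoint km --surv sim/survival.csv --baseline sim/baseline.csv --group sex --out km.csv
```

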
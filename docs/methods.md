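# Methods

## Model

The joint model couples a bivariate linear mixed model for systolic and
diastolic blood pressure (SBP/DBP) with a proportional-hazards model for
time to first remission, linked through the subject's *true* trajectory.

For subject i at visit time t (months since enrolment),

    Y_ij(t) = m_i(t) + eps_ij,   eps_ij ~ N(0, diag(sigma1^2, sigma2^2))
    m_i(t)  = X(t)'beta + Z(t)'b_i + u_i'delta

per marker, with X(t) = Z(t) = (1, t). The four random effects
(SBP intercept, SBP slope, DBP intercept, DBP slope) are jointly normal,
b_i ~ N(0, Sigma); their cross-correlations are what correlate the two
markers marginally. Measurement errors are independent across visits and
markers (no serial correlation beyond the random effects; nonlinear time
trends are out of scope). Because time enters linearly, each true
trajectory is a line m_k(t) = A_k + B_k t; the slope is the fixed time
coefficient plus the random slope, constant in t.

The hazard of first remission is

    h_i(t) = h0(t) exp[ gamma'u_i + rho . (m1(t), m1'(t), m2(t), m2'(t)) ]

— the "current value and slope" association, four coefficients. h0 is
piecewise constant between knots; value-only and slope-only association
structures are available via `MCMCConfig.association`.

Marginally, the observed markers at time t have covariance

    cov(Y1, Y2)(t) = w' Sigma_12 w,   w = (1, t)
    var(Y_k)(t)    = w' Sigma_kk w + sigma_k^2

which `marginal_covariance` evaluates; with the default (study-estimate)
variance components the implied SBP–DBP correlation is 0.2603 at the
first visit and 0.2468 one month later.

## Priors

N(0, 1000) on every longitudinal fixed effect, survival coefficient and
baseline log-hazard level. The association vector has the global–local
ridge shrinkage prior rho_s ~ N(0, tau psi_s) with
tau^-1 ~ Gamma(0.1, 0.1) and psi_s^-1 ~ Gamma(1, 0.01) (shape–rate):
the global scale tau pulls all four coefficients toward zero while the
local psi_s let individual coefficients escape. Priors the model needs
but that are genuinely open choices here: Sigma ~ inverse-Wishart(5, I)
and sigma_k^2 ~ inverse-Gamma(0.01, 0.01) — weakly-informative conjugate
defaults in the same spirit as the N(0, 1000) coefficients.

## Sampler

Metropolis-within-Gibbs, blocked as:

1. **Longitudinal fixed effects** (per marker): drawn from their Gaussian
   conjugate full conditional given the random effects and residual
   variance. Since beta also enters the hazard through m_i(t), the draw
   is treated as an independence proposal and accepted with the survival
   likelihood ratio; the correction is exact and degenerates to a plain
   conjugate draw when rho = 0.
2. **Interweaving re-centring**: the four (intercept, time) coefficients
   are re-drawn from their conditional in the non-centred
   parameterisation (b~_i = b_i + theta with b~_i ~ N(theta, Sigma)),
   then the random effects are shifted back. The trajectories m_i(t) are
   invariant under this move, so both likelihoods cancel and the step is
   pure conjugate. It removes the notoriously slow random-walk coupling
   between the centred intercepts and the random-effect means.
3. **Random effects b_i**: per-subject random-walk Metropolis,
   preconditioned by the current Cholesky factor of Sigma, with a
   per-subject step size adapted toward 0.234 acceptance during burn-in.
   All subjects are proposed and accepted/rejected in one vectorised pass.
4. **Residual variances**: conjugate inverse-Gamma.
5. **Sigma**: conjugate inverse-Wishart.
6. **Survival block** (baseline log-levels, gamma, rho): one adaptive
   Metropolis block whose proposal covariance is the running empirical
   covariance of the chain (learned during burn-in, then frozen), with a
   scalar scale adapted toward 0.234. Internally the block is sampled on
   a centred scale — marker values as deviations from their sample means,
   covariates as deviations from their column means — which removes the
   extreme ridge between rho and the baseline levels (an SBP near
   150 mmHg otherwise forces the baseline to absorb exp(rho*150)).
   Reported draws are transformed back to the original scale, and the
   N(0, 1000) prior is evaluated on the original baseline levels. The
   block is refreshed 5 times per sweep (`survival_updates`): it is cheap
   relative to the rest of the sweep and its parameters mix slowest.
7. **Shrinkage hyper-parameters**: exact Gamma full conditionals,
   tau^-1 ~ Gamma(0.1 + S/2, 0.1 + sum rho_s^2/(2 psi_s)) and
   psi_s^-1 ~ Gamma(1.5, 0.01 + rho_s^2/(2 tau)).

Random effects are integrated by sampling them within the chain (no
Laplace or quadrature marginalisation). Initialisation: per-marker least
squares for the fixed effects, per-subject least-squares residual fits
for b (which also seeds Sigma at a realistic scale — a zero start would
let the conjugate Sigma update collapse before the effects can grow), an
events-over-exposure exponential fit for the baseline levels, and rho = 0.
All chains are seeded by spawning from one master seed; runs are
bit-reproducible.

Defaults are 3 chains x 20,000 iterations (10,000 burn-in, thin 10).
The test suite and the recovery experiment use 2 chains x 4,000
iterations (2,000 burn-in, thin 5), which completes in about a minute at
n = 300 and is enough for the checks performed there; R-hat is reported
per parameter and flagged against 1.1, not silently accepted.

Cumulative hazards use 15-point Gauss–Legendre quadrature applied
piecewise between knots (and up to the event time). For the
piecewise-exponential-in-linear integrands this is accurate to ~1e-14,
verified against closed forms. Knots default to the quintiles of the
observed event times (count configurable); times beyond the last knot
use the last level.

## Synthetic cohort generator

The generator emulates a registry-style hypertension cohort of the kind
the model targets: n = 301 subjects, monthly visits at t = 0, 1, ..., 29,
administrative censoring at 30 months. Baseline categorical covariates
are drawn from the source cohort's observed margins (e.g. 50.8% male,
27.6% diabetes history); age is truncated-normal 51.77 (SD 13.88),
bounded at 15 years per the inclusion rule. Laboratory values are not
reported by the study, so their moments default to physiological
midpoints (e.g. sodium 140 (4) mmol/l) and are configurable.

Trajectory and hazard truth default to the published fitted model
(fixed effects, random-effect SDs 10.8131/0.8605/6.7399/0.5223 with the
reported correlations, residual SDs 15.0348/9.5268, SBP-value
association −0.1128). Event times are drawn from the hazard model itself
by inverse-transform sampling — Lambda_i(T) = −log(U) solved by
bracketed root finding — rather than from observed threshold crossings,
so that parameter-recovery experiments test exactly the model being
fitted; a threshold-based remission flag (first visit with observed
SBP < 140 and DBP < 90) is provided as a separate diagnostic
(`threshold_remission_times`). Visits after a subject's exit are
dropped, as in registry data. Optional exponential dropout is off by
default.

The constant default baseline log-hazard (13.6 on all five intervals)
was calibrated once so that the default cohort reproduces the study's
event rate (~80.7% by 30 months) and median remission time (~11 months);
the number is large only because it absorbs the association offset
exp(rho * SBP) at SBP ≈ 150.

What passing tests on these cohorts do **not** show: robustness to
missing-visit patterns, measurement rounding, informative dropout, or
nonlinear trajectories — none of which the generator emulates.

## Design choices and degenerate inputs

- Which covariates enter each marker follows the published fitted model
  (SBP includes diabetes/stroke/creatinine; DBP includes sodium/chlorine
  instead); the survival covariate set (sex, age, diabetes, drug type) is
  inferred from the reported hazard ratios. Both are configurable via
  `DesignSpec`.
- Reference-cell coding with the study's reference categories (female,
  rural, enalapril, monotherapy); continuous covariates are not
  standardised, matching the reported coefficient scales.
- Time is coded as months since enrolment with the first visit at t = 0;
  this convention reproduces the reported first-visit marginal
  correlation.
- Chi-square association tests apply the Yates continuity correction
  exactly for 2x2 tables (the convention that reproduces the study's
  descriptive statistics); the behaviour is exposed as a flag.
- The survival sample-size formula n = 4(z_{a/2}+z_power)^2/(p theta^2)
  with the study's stated inputs gives 367; the study nevertheless used
  301 subjects, which this package keeps only as the default cohort size.
- Model comparison uses DIC (conditional, at the posterior means of
  parameters and random effects) and WAIC from per-subject pointwise
  log-likelihood draws.
- Degenerate inputs: all-censored data raise an identifiability error
  (no baseline hazard information); zero-probability categories,
  non-positive-definite covariances, empty visit schedules, horizons
  before the prediction landmark, and id mismatches across tables all
  raise typed errors rather than propagating NaNs.

## Dynamic prediction

`dynamic_prediction` estimates S(u | T > t, history): for each posterior
draw (or a fixed parameter point), the subject's random effects are
sampled by short Metropolis runs targeting their conditional given the
observed pressure history and survival to t, then
exp(−(Lambda(u) − Lambda(t))) is averaged over draws, with 2.5%/97.5%
quantile bands. With zero association it reduces exactly to the baseline
survival ratio, which the tests verify against the closed form.

## Known limitations

- The per-parameter "SE" of the source study's summary table is of
  unclear definition (its magnitudes are inconsistent with the printed
  credible intervals); the summary here reports the posterior SD and a
  Monte-Carlo SE separately and does not attempt to match that column.
- The reported third-visit marginal correlation (0.244) is not
  reproducible under any monthly-visit time coding (the model implies
  ~0.236 at t = 2); the first two visits are reproduced exactly.
- Single-marker models, competing risks, recurrent remissions and
  time-varying exogenous covariates in the hazard are out of scope.
- At small n (tens of subjects) the posterior of the random-effect
  correlations mixes slowly; the R-hat column of `summary()` should be
  consulted before interpreting those entries.
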
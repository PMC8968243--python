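# Methods

This note records the statistical models, the numerical choices behind
the estimators, and the scope and limits of the synthetic data
generator. It is the package's own account of what is computed and why
the defaults are what they are.

## 1. Choice setting

Each task shows two vaccine profiles (A, B) and an opt-out. A profile
has nine attributes: out-of-pocket cost ($0/50/100/175), effectiveness
(20/40/60/80%), incubation period (7/14/21 days), protection duration
(3/6/12 months), mild side effects per 10 (1/3/5), severe side effects
per million (1/10/100), recommending body (personal doctor as base;
CDC, WHO, media), country of origin (Germany as base; USA, UK, China),
and months since introduction (3/6).

Utility of vaccine `j` for respondent `i` in task `t`:

```
u_ijt = x_ijt' (beta + Pi w_i) + e_ijt
u_i0t = delta_io + w_i' gamma + e_i0t
```

with iid type-I extreme-value errors, so task choices are multinomial
logit conditional on `delta_io`. Three interactions enter `Pi`: cost x
high household income (>= $120,000), effectiveness x second survey
wave, and China origin x Republican. Household income enters `gamma` in
units of $10,000. Model variants: `cl1`/`rpl1` treat cost linearly;
`cl2`/`rpl2` add a free-vaccine dummy (cost = 0).

## 2. Estimators

### Conditional logit

`delta_io = delta_o` fixed. The log-likelihood is globally concave;
estimation is Newton's method from a zero start with analytic gradient
and Hessian, stopping at max|gradient| < 1e-6. Coefficients whose
magnitude exceeds 12 trigger a separation warning (a dummy that
perfectly predicts choices sends its coefficient to infinity).
Standard errors come from the inverse negative Hessian.

### Panel mixed logit (random opt-out constant)

`delta_io ~ N(delta_o, sigma_o^2)`, drawn once per respondent and
shared across their tasks — a panel random effect capturing stable
individual vaccine hesitancy. The per-respondent likelihood is the
integral of the product of task probabilities over the constant,
simulated with R draws:

```
ll_i = log (1/R) sum_r prod_t P(chosen_it | delta_o + sigma_o z_ir)
```

Numerical choices:

- **Draws.** Shifted Halton deviates (base-3 radical inverse, first 10
  points discarded, one seeded uniform shift per draw set). Quasi-Monte
  Carlo error decays roughly like 1/R for this smooth one-dimensional
  integral versus 1/sqrt(R) for pseudo-random draws; internal checks
  show doubling the draws moves the log-likelihood by less than the
  pseudo-random Monte Carlo standard error at the same R.
- **Optimizer.** BFGS with the analytic simulated-likelihood gradient,
  warm-started from the conditional-logit estimates, gtol = 1e-5. At a
  log-likelihood of order 1e4, float64 summation noise makes a 1e-6
  gradient floor unreliable; 1e-5 is the tightest dependable setting.
  BFGS "precision loss" exits with max|gradient| < 10 x gtol are
  reported as converged. The spread is parameterized as `|s|` so the
  search is unconstrained while the reported `sigma_o` is nonnegative.
- **Quadrature cross-check.** The same likelihood kernel evaluates on
  Gauss-Hermite nodes. At the stored `sigma_o ~ 3.3` the integrand is
  wide, so coarse rules are not converged: acceptance checks use
  200-node quadrature against R = 200,000 Halton draws (relative
  agreement ~1e-6, threshold 1e-4). Node weights that underflow to zero
  (beyond ~350 nodes) are dropped before taking logs.

### Latent-class conditional logit

`Q` classes, each a conditional logit whose opt-out carries only a
class-specific constant; respondent covariates enter a
multinomial-logit membership model with class 1 as reference.
Estimation is EM: the E-step computes responsibilities from per-class
panel likelihoods and membership priors; the M-step runs weighted
Newton conditional-logit fits per class and a weighted multinomial
logit for membership. The observed-data log-likelihood is ascended
monotonically (asserted in tests). Defaults: 10 Dirichlet(1) random
responsibility starts (seeded), tolerance 1e-8 on the relative
log-likelihood change. A class whose expected share falls below 0.5%
triggers a warning that `Q` likely exceeds what the data support.
Standard errors use the Fisher-identity score (the gradient of the
observed-data log-likelihood equals the responsibility-weighted
complete-data score) differentiated numerically.

### Model selection

`BIC = -2 ll + k ln(n)` with `n` = number of choice tasks (the number
of independent likelihood contributions under the conditional-logit
sampling view; a convention, documented rather than tuned). Selection
tables report all fitted models sorted by BIC.

## 3. Post-estimation

- **WTP.** For attribute `k`, WTP = -(beta_k + pi_k d) / beta_cost,
  where `d` switches on an interaction (wave 2, Republican x China) and
  the high-income group's cost coefficient includes the cost x
  high-income interaction. Standard errors use the delta method on the
  ratio. Ratios of 4-decimal printed coefficients are reproducible only
  to ~2%; cells whose denominator is itself a sum of rounded values
  (the high-income group) carry a wider rounding-propagated bound.
- **Odds ratios.** exp of the opt-out index coefficients (and exp of
  `sigma_o` for mixed fits); exp of membership coefficients for class
  assignment odds. Confidence intervals are exp(coef +/- 1.96 SE).
- **Posterior classes.** Bayes' rule over per-class panel likelihoods;
  `assign_classes` draws one label per respondent from the posterior
  with a caller-provided seed.
- **Scenario curves.** Population-average P(A), P(B), P(opt-out) for a
  representative individual while one attribute of A moves along a
  grid. For mixed-logit parameters the average over the random constant
  uses 30-node Gauss-Hermite quadrature by default; the Monte Carlo
  alternative uses seeded randomized-Halton deviates (plain
  pseudo-random draws at R = 10,000 leave ~5e-3 error, above the 1e-3
  agreement the quadrature cross-check demands; the quasi-Monte Carlo
  error is ~1e-5). Curve crossings are located by linear interpolation
  between grid points.

## 4. Synthetic generator

Scope: the generator exists to exercise and audit the estimators, not
to reproduce the original sample's answers.

- **Design.** 24 cards of two profiles each, attributes assigned
  level-balanced with seeded shuffles; cards that would pair identical
  profiles are repaired by re-drawing one attribute (which can leave a
  level count off balance by up to two). Each respondent answers 7
  distinct cards.
- **Population.** Defaults follow the study's sample: n = 2,723; the
  second survey wave is the trailing block of 1,049 respondents; binary
  covariates are independent Bernoulli draws at the study's sample
  shares (education postgraduate = master's 15.28% + doctoral 2.46%);
  party affiliation is a three-way categorical (Democrat 42.09%,
  Republican 29.93%). Three shares the study does not report are set
  once to plausible US values: religion extremely important 0.25, over-65
  household member 0.15, underlying condition 0.30. Age is drawn
  uniformly within generation bands at the study's generation shares;
  household income is lognormal with median $45,000 and log-sd 0.9; BMI
  is normal (31, 6) floored at 15. **Limit:** covariates are sampled
  independently, so joint structure (income x education, age x party)
  is absent; aggregate outcomes that depend on these correlations — the
  opt-out share in particular — will not match the original sample
  (under the stored mixed-logit point the synthetic acceptance rate is
  ~2/3 versus the study's reported 71.67%).
- **Simulation.** Choices are drawn from the exact logit probabilities;
  the returned truth records probabilities, realized random constants
  and class labels, enabling oracle tests (aggregate chosen counts
  match summed probabilities within binomial error; scaled-up utilities
  make the modal alternative deterministic).
- **Recovery audit.** `recovery_experiment` repeats
  simulate-and-refit and reports bias, RMSE, SE calibration, coverage
  and max |estimate - truth| / SE per parameter. Acceptance runs use
  n = 2,000 respondents x 7 tasks with 3 replicates per estimator
  (mixed logit at R = 200 draws). Because ~120 deviation/SE comparisons
  are made simultaneously, the pass condition is family-wise (max |z| <
  4.5, at most two comparisons beyond 3 SE) rather than per-comparison.

## 5. Known limitations

- Only the opt-out constant is random in the mixed logit; attribute
  coefficients are fixed (as in the model this package follows).
- LCL standard errors ignore the first-stage uncertainty interaction
  between class-specific blocks beyond what the outer-product/numerical
  Hessian of the observed-data score captures near the EM fixed point.
- The synthetic population's independence assumption above.
- Printed-coefficient post-estimation carries no covariance, so those
  tables omit standard errors and confidence intervals (a warning is
  emitted).
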
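# Methods

## The task environment

The package models a restless four-armed bandit: on each of 300 trials
(four blocks of 75) the agent picks one of four bandits and receives an
integer point payoff. Each bandit's mean payoff follows a decaying Gaussian
random walk,

    mu[i, t+1] = lambda * mu[i, t] + (1 - lambda) * theta + v_t,
    v_t ~ N(0, sigma_d^2),      r[i, t] ~ N(mu[i, t], sigma_o^2),

with defaults lambda = 0.9836, theta = 50, sigma_o = 4, sigma_d = 2.8.
This is an AR(1) process with stationary mean theta and stationary sd
sigma_d / sqrt(1 - lambda^2) ~= 15.5, so payoffs hover in the 0–100 display
range without clipping; clipping would distort the generative model and is
deliberately not applied. Realized payoffs are rounded to the nearest
integer and floored at zero (the task displays integer points); latent means
stay continuous. Points convert to money at 5 cents per 100 points, rounded
half-up to whole cents.

Initial latent means are drawn uniformly within two stationary standard
deviations of the decay center. The three payoff-walk instantiations used in
the original task are not recoverable, so walks are regenerated from the
stated process; one master seed derives independent streams for initial
means, diffusion noise, observation noise, subject parameters and choices,
making every simulation bit-reproducible.

## Learning rules

**Kalman (Bayesian) learner.** Each bandit carries a Gaussian prior belief
N(mu_pre, sigma2_pre). Observing reward r for the chosen bandit c applies
the conjugate update

    kappa = sigma2_pre / (sigma2_pre + sigma_o_hat^2)
    mu_post = mu_pre + kappa * (r - mu_pre),   sigma2_post = (1 - kappa) * sigma2_pre

while unchosen bandits keep their priors within the trial. Between trials
all four bandits drift according to the agent's model of the walk:
mu_pre' = lambda_hat * mu_post + (1 - lambda_hat) * theta_hat and
sigma2_pre' = lambda_hat^2 * sigma2_post + sigma_d_hat^2. The learner
parameters (lambda_hat, theta_hat, sigma_o_hat^2, sigma_d_hat^2) are fixed
at the true generative values, and the initial prior is fixed at
N(50, 15.52^2) — mean at the decay center, sd at the stationary value.
Fixing the initial prior (rather than estimating it) stabilizes the
hierarchical fits and matches the treatment of these quantities as fixed
model constants.

**Delta learner.** The chosen bandit's point value moves by a constant
fraction of the prediction error, v <- v + alpha (r - v), with free
learning rate alpha in [0, 1] and v1 = 50 for all bandits (the decay
center; a symmetric start). The Delta rule tracks no uncertainty of its
own; for the choice rules that need an uncertainty signal, the Kalman
variance recursion supplies it. This is a principled pairing because the
variance recursion is reward-free — it depends only on which bandits were
chosen and on the fixed variance parameters — so it adds no free parameters
and is identical across subjects given the same choice history.

**Missed trials** receive no within-trial update (no reward was observed);
the between-trial drift still applies, and the trial is excluded from the
likelihood and from all percentage denominators.

## Choice rules

All four rules are softmax policies over an augmented value per bandit:

    rule 1 (SM)    beta * mu_i
    rule 2 (SME)   beta * [mu_i + phi sigma_i]
    rule 3 (SMEP)  beta * [mu_i + phi sigma_i + I(c_prev = i) rho]
    rule 4 (SMERP) beta * [mu_i + phi sigma_i + I(c_prev = i) rho
                           + gamma mu_i / sum_j sigma_j]

beta >= 0 is the inverse temperature (random exploration), phi weights the
uncertainty bonus (directed exploration), rho is a constant perseveration
bonus for the previously chosen bandit, and gamma scales a second
random-exploration term discounted by the total uncertainty, in the spirit
of Thompson sampling. Two conventions worth making explicit:

* the inverse temperature multiplies the **full** augmented value in every
  rule (the rule-3 form extended consistently to rules 2 and 4);
* the rule-4 term uses each bandit's own mu_i in its bracket, with the
  denominator the sum of all four prior sds on that trial.

On a session's first trial there is no previous choice and the
perseveration indicator is zero for all bandits. All probabilities are
computed with log-sum-exp stabilization; inside log-likelihoods only,
probabilities are floored at machine epsilon (never in simulation).

Crossing the two learners with the four rules yields the eight models of
the registry (`delta-sm` … `bayes-smerp`).

## Synthetic cohorts

The generator emulates the study structure: a within-subjects cohort
(default 31 subjects) under three conditions (placebo, ldopa, haloperidol),
each condition with its own payoff walk shared by all subjects. Subject
parameters are drawn from condition-specific group normals
N(M_x, Lambda_x), truncated by resampling only where the parameter has a
bounded support (beta >= 0, alpha in [0, 1]); signed parameters (phi, rho,
gamma) are untruncated, since a signed directed-exploration weight is
exactly what a drug-induced attenuation can produce.

Default ground truth: M_beta = 0.29, M_phi = 1.34, M_rho = 4.11 with
Lambda = (0.1, 0.5, 1.5). The means are plausible single-subject posterior
medians repurposed as group means — synthetic choices, not fitted group
estimates, which are not available in numeric form. `emulate_study_effect`
builds the drug-effect scenario by scaling M_phi in the ldopa condition by
(1 - reduction), default 0.5, leaving everything else identical across
conditions. Response omissions are simulated at a configurable rate
(default 0).

## Hierarchical inference

Per condition (conditions are fitted independently — no cross-condition
pooling), the model is

    x_s ~ Normal(M_x, Lambda_x)  restricted to the parameter's support,
    M_x ~ Uniform(lower_x, upper_x),
    Lambda_x ~ half-Cauchy(0, 1),

with default group-mean bounds alpha in [0,1], beta in [0,3],
phi in [-10,10], rho in [-15,15], gamma in [-10,10] — wide enough to cover
plausible fitted values, and configurable. Support restriction is by
rejection without renormalizing the truncated normal, the same convention
a bounded-parameter declaration produces in Stan-style samplers.

Sampling uses ensemble MCMC (`emcee`, differential-evolution and snooker
moves) over a non-centered parameterization: subject offsets
z_s = (x_s - M) / Lambda with standard-normal priors, and Lambda on the log
scale with the Jacobian included. The non-centered form avoids the funnel
geometry that hierarchical scale parameters induce. Because the Kalman
learner's belief trajectory contains no free choice parameters, each
subject's sequence is reduced once to per-trial features and the likelihood
of a whole ensemble of parameter vectors is a single broadcasted softmax
evaluation; Delta-learner mean trajectories are recomputed per batch with a
vectorized recursion over trials.

Walkers are initialized around per-subject penalized maximum-likelihood
estimates (L-BFGS-B within the prior bounds, weak Gaussian penalty with
sd 10 to regularize flat directions). Independent ensemble runs play the
role of chains; the default budget is 4 chains x 1000 warmup steps with
1000 retained draws per chain, and a reduced test profile uses 2 chains x
250/250. Retained draws are subsampled evenly over post-warmup steps and
walkers. Diagnostics: split-R-hat and bulk ESS per group-level parameter
(target R-hat <= 1.01, hard failure above 1.1 — reported loudly, never
silently), plus the mean acceptance fraction. Divergent transitions are a
Hamiltonian-sampler concept with no ensemble analogue and are reported as
zero/not-applicable.

Condition contrasts are highest-density intervals (shortest interval, 90%
mass by default) of the draw-wise difference of group means between two
conditions, with a flag for excluding zero.

## Model comparison

Approximate leave-one-out cross-validation with the unit defined as one
subject under one condition, compounded over trials (per-trial LOO is a
diagnostic option only). Importance ratios are smoothed with a
generalized-Pareto fit to the largest 20% of ratios (PSIS, via
`arviz.psislw`); units with Pareto k > 0.7 are flagged. Totals are reported
both raw and per data point (divided by the summed responded-trial counts);
the per-point normalization does not change the ranking. Pairwise model
differences carry standard errors computed from per-unit elpd differences.
Posteriors with numerically identical likelihood draws yield uniform
weights; LOO then equals the in-sample log-likelihood and the result is
flagged degenerate.

## Trial classification and behavioral metrics

A responded trial is **exploitation** when the chosen bandit attains the
maximum prior mean (ties — which arise at trial 1, when all beliefs are
equal — count as exploitation). Exploration trials are **directed** when
the chosen bandit attains the maximum prior sd over all four bandits, else
**random**. Exploitation takes precedence: a bandit maximizing both value
and uncertainty is exploitation, because the directed/random split is
defined only within exploration trials. Trial 1 is excluded from block
summaries of exploration fractions by default. Model-free metrics: percent
choices of the objectively best bandit (highest latent mean) per block
(trials 1–10, 11–50, then five 50-trial blocks), percent choice switches
(responded trials only), and total payout.

## Numerical and scaling choices

* Tie tolerance in argmax classification: 1e-12 (ties are measure-zero with
  continuous beliefs except at trial 1).
* MAP optimization: 2–4 random restarts; bound hits are flagged.
* The test suite and the bundled checks run at reduced problem sizes chosen
  to exercise every code path at full trial counts where it matters:
  parameter recovery uses three independent 8-subject x 300-trial cohorts
  with the 2-chain 250/250 sampler profile (coverage is assessed across the
  repetitions, since a single cohort's group-mean interval covers the
  population value only at its nominal rate); model recovery uses ten
  5-subject x 150-trial cohorts; the drug-effect contrast uses 12 subjects
  x 225 trials in two conditions; the exact-LOO cross-check uses 3 subjects
  x 40 trials. The full 31-subject x 300-trial x 3-condition profile runs
  through the same code paths via the `full` pipeline profile.

## What the synthetic generator does and does not capture

The generator reproduces the study's structure (within-subjects roster,
per-condition walks, trial counts, the group-level parameter hierarchy and
a condition-specific reduction of directed exploration). It does not model
reaction times, session-order or counterbalancing effects, drug
pharmacokinetics, time-on-task drifts in the parameters, or any departure
of real subjects from the fitted model class. Passing recovery tests
therefore shows that the estimation machinery is correct and well-scaled
for data of this kind, not that real choice data satisfy the model's
assumptions.

## Known limitations

* Ensemble MCMC mixes more slowly than gradient-based samplers on the
  richest models (five subject-level parameters) at very small data sizes;
  the hard R-hat gate surfaces this rather than hiding it.
* Group-level means of bounded parameters (beta near 0) inherit a mild
  boundary interaction from the unnormalized-truncation convention; with
  realistic data the posterior mass sits far from the boundary.
* LOO units hold out whole subject-condition blocks; Pareto k values grow
  with block length, and the exact-LOO agreement check conditions on
  k below the reliability threshold.
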
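# restless-bandits

Simulation, hierarchical Bayesian fitting and comparison of explore/exploit
models for the restless four-armed bandit task.

## The problem

In a restless bandit, the mean payoffs of four options drift over time as a
decaying Gaussian random walk (decay 0.9836 toward 50, diffusion sd 2.8,
observation sd 4), so an agent must keep balancing **exploitation** of the
currently best option against **exploration** of alternatives whose values
have become uncertain. This package is for computational cognitive
scientists who want to model that behavior: it implements eight cognitive
models — two learning rules (constant-learning-rate Delta rule, and a
Kalman filter that additionally tracks each option's uncertainty) crossed
with four softmax choice rules

    SM     P(i) ∝ exp(β μᵢ)
    SME    P(i) ∝ exp(β [μᵢ + φ σᵢ])
    SMEP   P(i) ∝ exp(β [μᵢ + φ σᵢ + I(cₜ₋₁=i) ρ])
    SMERP  P(i) ∝ exp(β [μᵢ + φ σᵢ + I(cₜ₋₁=i) ρ + γ μᵢ / Σⱼσⱼ])

where β captures random exploration, φ a directed-exploration
(uncertainty) bonus, ρ choice perseveration, and γ total-uncertainty-scaled
random exploration. Around the models it provides:

* a seeded task/walk generator and a synthetic-cohort generator with known
  ground truth, including an "L-dopa-like" scenario that attenuates the
  group-level directed-exploration weight in one condition;
* hierarchical Bayesian estimation (subject-level parameters drawn from
  per-condition group normals N(M, Λ); uniform priors on M, half-Cauchy(0,1)
  on Λ) by ensemble MCMC, with split-R̂/ESS diagnostics and 90% HDI
  condition contrasts;
* PSIS-LOO model comparison with one held-out unit = one subject in one
  condition;
* model-based trial classification (exploit / directed / random
  exploration), trial-wise fMRI-style regressors (μ^pre, σ^pre, prediction
  error δ, choice probability, total uncertainty Σσ^pre), and model-free
  behavioral metrics.

## Worked example

Simulate a two-condition cohort in which the directed-exploration weight φ
is halved under "ldopa", fit the Kalman-filter model with exploration and
perseveration bonuses (`bayes-smep`), and test the condition contrast:

```python
import numpy as np
from restless_bandits import (
    CohortSpec, emulate_study_effect, simulate_cohort,
    fit_hierarchical, condition_contrast_hdi,
)
from restless_bandits.inference import SamplerConfig

spec = emulate_study_effect(
    CohortSpec(n_subjects=12, conditions=("placebo", "ldopa"), seed=99),
    reduction=0.5,
)
cohort = simulate_cohort(spec)          # ground truth: M_phi 1.34 vs 0.67
fit = fit_hierarchical(
    cohort.data, model="bayes-smep",
    sampler=SamplerConfig(n_chains=2, n_warmup=250, n_samples=250, seed=99),
)
for p in ("beta", "phi", "rho"):
    print(p, np.median(fit.group_draws(p, "placebo")).round(2),
          np.median(fit.group_draws(p, "ldopa")).round(2))
res = condition_contrast_hdi(fit, "phi", "placebo", "ldopa", mass=0.90)
print("phi contrast 90% HDI:", np.round(res.interval, 2),
      "excludes zero:", res.excludes_zero)
```

Output (300-trial sessions):

```
beta 0.27 0.38
phi 1.26 0.74
rho 3.83 3.7
phi contrast 90% HDI: [0.3  0.71] excludes zero: True
```

The posterior group medians track the generating values (β 0.29, ρ 4.11
shared across conditions; φ 1.34 under placebo vs 0.67 under ldopa), and
the 90% highest-density interval of the group-mean difference
M_φ(placebo) − M_φ(ldopa) lies above zero — the fitted model detects the
built-in attenuation of directed exploration.

The same flow is available from a shell:

```sh
restless-bandit run --out-dir runs/demo --seed 1 \
    --n-subjects 12 --conditions placebo,ldopa --phi-reduction 0.5
```

which writes the dataset, walks, per-model posterior draws, a LOO table
(with `--model all8`), trial-wise regressor TSVs and a behavioral summary
into `runs/demo/`.

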
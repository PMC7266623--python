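"""Softmax choice rules mapping belief states to choice probabilities.

All four rules are softmax policies over an augmented value per bandit i,

    rule 1 (SM):     beta * mu_i
    rule 2 (SME):    beta * [mu_i + phi * sigma_i]
    rule 3 (SMEP):   beta * [mu_i + phi * sigma_i + I(c_prev = i) * rho]
    rule 4 (SMERP):  beta * [mu_i + phi * sigma_i + I(c_prev = i) * rho
                             + gamma * mu_i / sum_j sigma_j]

where mu_i / sigma_i are the pre-choice prior mean and sd, beta is the inverse
temperature (random exploration), phi weights the uncertainty bonus (directed
exploration), rho is a constant perseveration bonus for the previously chosen
bandit, and gamma scales a second random-exploration term discounted by the
total uncertainty over all bandits.  The inverse temperature multiplies the
full augmented value in every rule.  On a session's first trial there is no
previous choice and the perseveration term is absent.

Crossing the two learners (Delta, Bayes) with the four rules yields the eight
models of the registry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from restless_bandits.learning import LearnerParams, run_learner

__all__ = [
    "ChoiceParams",
    "ModelSpec",
    "MODEL_REGISTRY",
    "list_models",
    "choice_prob_sm",
    "choice_prob_sme",
    "choice_prob_smep",
    "choice_prob_smerp",
    "choice_probabilities",
    "log_likelihood",
]

#: probability floor used inside log-likelihoods only (never in simulation)
_LOG_FLOOR = np.finfo(float).eps


@dataclass(frozen=True)
class ChoiceParams:
    """Choice-rule parameters; parameters a rule does not use stay None."""

    beta: float
    phi: float | None = None
    rho: float | None = None
    gamma: float | None = None
    previous_choice: int | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logsumexp(logits)
    return np.exp(z)


def _check_finite(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def choice_prob_sm(means: np.ndarray, beta: float) -> np.ndarray:
    """Rule 1: plain softmax over beta * mu."""
    means = _check_finite("means", means)
    return _softmax(beta * means)


def choice_prob_sme(
    means: np.ndarray, sds: np.ndarray, beta: float, phi: float
) -> np.ndarray:
    """Rule 2: softmax with directed-exploration bonus phi * sigma."""
    means = _check_finite("means", means)
    sds = _check_finite("sds", sds)
    if np.any(sds <= 0):
        raise ValueError("sds must be > 0")
    return _softmax(beta * (means + phi * sds))


def choice_prob_smep(
    means: np.ndarray,
    sds: np.ndarray,
    beta: float,
    phi: float,
    rho: float,
    previous_choice: int | None = None,
) -> np.ndarray:
    """Rule 3: rule 2 plus a perseveration bonus rho for the previous choice."""
    means = _check_finite("means", means)
    sds = _check_finite("sds", sds)
    if np.any(sds <= 0):
        raise ValueError("sds must be > 0")
    value = means + phi * sds
    if previous_choice is not None:
        value = value.copy()
        value[previous_choice] += rho
    return _softmax(beta * value)


def choice_prob_smerp(
    means: np.ndarray,
    sds: np.ndarray,
    beta: float,
    phi: float,
    rho: float,
    gamma: float,
    previous_choice: int | None = None,
) -> np.ndarray:
    """Rule 4: rule 3 plus gamma * mu / (total uncertainty) per bandit."""
    means = _check_finite("means", means)
    sds = _check_finite("sds", sds)
    if np.any(sds <= 0):
        raise ValueError("sds must be > 0")
    total_sd = sds.sum()
    value = means + phi * sds + gamma * means / total_sd
    if previous_choice is not None:
        value[previous_choice] += rho
    return _softmax(beta * value)


def choice_probabilities(
    rule: str, means: np.ndarray, sds: np.ndarray | None, params: ChoiceParams
) -> np.ndarray:
    """Dispatch on rule name ('sm', 'sme', 'smep', 'smerp')."""
    if rule == "sm":
        return choice_prob_sm(means, params.beta)
    if rule == "sme":
        return choice_prob_sme(means, sds, params.beta, params.phi)
    if rule == "smep":
        return choice_prob_smep(
            means, sds, params.beta, params.phi, params.rho, params.previous_choice
        )
    if rule == "smerp":
        return choice_prob_smerp(
            means,
            sds,
            params.beta,
            params.phi,
            params.rho,
            params.gamma,
            params.previous_choice,
        )
    raise ValueError(f"unknown choice rule {rule!r}")


@dataclass(frozen=True)
class ModelSpec:
    """One of the eight cognitive models: a learner crossed with a rule."""

    name: str
    learner: str  # 'delta' or 'bayes'
    rule: str  # 'sm', 'sme', 'smep', 'smerp'
    free_params: tuple[str, ...]

    @property
    def display_name(self) -> str:
        return f"{self.learner.capitalize()}-{self.rule.upper()}"


def _build_registry() -> dict[str, ModelSpec]:
    rule_params = {
        "sm": ("beta",),
        "sme": ("beta", "phi"),
        "smep": ("beta", "phi", "rho"),
        "smerp": ("beta", "phi", "rho", "gamma"),
    }
    registry: dict[str, ModelSpec] = {}
    for learner in ("delta", "bayes"):
        for rule, params in rule_params.items():
            name = f"{learner}-{rule}"
            free = (("alpha",) if learner == "delta" else ()) + params
            registry[name] = ModelSpec(
                name=name, learner=learner, rule=rule, free_params=free
            )
    return registry


MODEL_REGISTRY: dict[str, ModelSpec] = _build_registry()


def list_models() -> list[str]:
    """Names of the eight models (2 learners x 4 choice rules)."""
    return list(MODEL_REGISTRY)


def log_likelihood(
    choices: np.ndarray,
    rewards: np.ndarray,
    responded: np.ndarray | None = None,
    *,
    model: str = "bayes-smep",
    params: dict[str, float] | None = None,
    learner_params: LearnerParams = LearnerParams(),
    n_bandits: int = 4,
) -> float:
    """Log-likelihood of one subject-condition sequence under a model.

    Sum over responded trials of the log choice probability of the chosen
    bandit; missed trials contribute nothing (and break no perseveration
    chain beyond the last *responded* choice).  Probabilities are floored at
    machine epsilon inside the log, so degenerate parameters yield a large
    negative (finite) value rather than silent -inf unless the probability is
    exactly zero by construction.
    """
    spec = MODEL_REGISTRY[model]
    params = dict(params or {})
    missing = [p for p in spec.free_params if p not in params]
    if missing:
        raise ValueError(f"model {model!r} requires parameters {missing}")

    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=float)
    if responded is None:
        responded = np.ones(choices.size, dtype=bool)
    responded = np.asarray(responded, dtype=bool)

    traj = run_learner(
        choices,
        rewards,
        responded,
        learner_params,
        kind=spec.learner,
        alpha=params.get("alpha"),
        n_bandits=n_bandits,
    )
    cp = ChoiceParams(
        beta=params["beta"],
        phi=params.get("phi"),
        rho=params.get("rho"),
        gamma=params.get("gamma"),
    )
    total = 0.0
    prev: int | None = None
    for t in range(choices.size):
        if not responded[t]:
            continue
        cp_t = ChoiceParams(
            beta=cp.beta, phi=cp.phi, rho=cp.rho, gamma=cp.gamma, previous_choice=prev
        )
        p = choice_probabilities(spec.rule, traj.mu_pre[t], traj.sigma_pre[t], cp_t)
        total += float(np.log(max(p[choices[t]], _LOG_FLOOR)))
        prev = int(choices[t])
    return total
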
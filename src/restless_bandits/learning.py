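"""Learning rules: Kalman-filter (Bayesian) and Delta-rule value tracking.

The Kalman learner carries a Gaussian prior belief N(mu_pre, sigma2_pre) per
bandit.  Observing reward r for the chosen bandit c gives the conjugate update

    kappa = sigma2_pre / (sigma2_pre + sigma_o^2)        (Kalman gain)
    mu_post = mu_pre + kappa * (r - mu_pre)
    sigma2_post = (1 - kappa) * sigma2_pre

while unchosen bandits keep their priors within the trial.  Between trials all
bandits drift according to the subject's model of the random walk:

    mu_pre'    = lambda_hat * mu_post + (1 - lambda_hat) * theta_hat
    sigma2_pre' = lambda_hat^2 * sigma2_post + sigma_d_hat^2

The Delta learner replaces the gain with a constant learning rate alpha and
tracks point values only; when an uncertainty signal is needed (exploration
bonus choice rules) the Kalman variance recursion — which is reward-free and
fully determined by the fixed variance parameters — supplies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearnerParams",
    "KalmanState",
    "DeltaState",
    "UpdateRecord",
    "Trajectory",
    "kalman_gain",
    "kalman_observe",
    "kalman_drift",
    "delta_update",
    "run_learner",
]

_DEFAULT_LAMBDA = 0.9836
_DEFAULT_DIFF_VAR = 2.8**2


def _stationary_sd(diff_var: float, lam: float) -> float:
    return math.sqrt(diff_var / (1.0 - lam**2))


@dataclass(frozen=True)
class LearnerParams:
    """Fixed learner parameters (subject's model of the environment).

    Defaults equal the true generative values: lambda_hat = 0.9836,
    theta_hat = 50, sigma_o_hat^2 = 16, sigma_d_hat^2 = 7.84, and an initial
    prior N(50, sd^2) with sd at the walk's stationary value (~15.52).
    """

    est_lambda: float = _DEFAULT_LAMBDA
    est_center: float = 50.0
    est_obs_var: float = 16.0
    est_diff_var: float = _DEFAULT_DIFF_VAR
    init_mean: float = 50.0
    init_sd: float = _stationary_sd(_DEFAULT_DIFF_VAR, _DEFAULT_LAMBDA)

    def __post_init__(self) -> None:
        if not 0.0 < self.est_lambda <= 1.0:
            raise ValueError(f"est_lambda must lie in (0, 1], got {self.est_lambda}")
        for name in ("est_obs_var", "est_diff_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.init_sd <= 0:
            raise ValueError(f"init_sd must be > 0, got {self.init_sd}")


@dataclass(frozen=True)
class KalmanState:
    """Per-bandit prior belief: mean (points) and variance (points^2)."""

    prior_mean: np.ndarray
    prior_var: np.ndarray

    def __post_init__(self) -> None:
        pm = np.asarray(self.prior_mean, dtype=float)
        pv = np.asarray(self.prior_var, dtype=float)
        if pm.shape != pv.shape or pm.ndim != 1:
            raise ValueError("prior_mean and prior_var must be 1-D and congruent")
        if np.any(pv <= 0):
            raise ValueError("prior_var must be positive for all bandits")
        object.__setattr__(self, "prior_mean", pm)
        object.__setattr__(self, "prior_var", pv)

    @classmethod
    def initial(cls, params: LearnerParams, n_bandits: int = 4) -> "KalmanState":
        return cls(
            prior_mean=np.full(n_bandits, params.init_mean),
            prior_var=np.full(n_bandits, params.init_sd**2),
        )


@dataclass(frozen=True)
class DeltaState:
    """Per-bandit point values with a constant learning rate alpha in [0, 1]."""

    value: np.ndarray
    learning_rate: float

    def __post_init__(self) -> None:
        v = np.asarray(self.value, dtype=float)
        if v.ndim != 1:
            raise ValueError("value must be 1-D")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError(
                f"learning_rate must lie in [0, 1], got {self.learning_rate}"
            )
        object.__setattr__(self, "value", v)

    @classmethod
    def initial(
        cls, learning_rate: float, n_bandits: int = 4, v1: float = 50.0
    ) -> "DeltaState":
        return cls(value=np.full(n_bandits, v1), learning_rate=learning_rate)


@dataclass(frozen=True)
class UpdateRecord:
    """Within-trial update of the chosen bandit."""

    kalman_gain: float
    prediction_error: float
    posterior_mean: float
    posterior_var: float


def kalman_gain(prior_var: float, obs_var: float) -> float:
    """kappa = prior_var / (prior_var + obs_var), strictly in (0, 1)."""
    if prior_var <= 0:
        raise ValueError(f"prior_var must be > 0, got {prior_var}")
    if obs_var <= 0:
        raise ValueError(f"obs_var must be > 0, got {obs_var}")
    return prior_var / (prior_var + obs_var)


def kalman_observe(
    state: KalmanState, chosen: int, reward: float, params: LearnerParams
) -> tuple[KalmanState, UpdateRecord]:
    """Conjugate within-trial update of the chosen bandit's belief.

    Unchosen bandits' posteriors equal their priors for the trial.
    """
    if not 0 <= chosen < state.prior_mean.size:
        raise IndexError(f"chosen bandit {chosen} out of range")
    if not math.isfinite(reward):
        raise ValueError(f"reward must be finite, got {reward!r}")
    kappa = kalman_gain(state.prior_var[chosen], params.est_obs_var)
    delta = reward - state.prior_mean[chosen]
    mean = state.prior_mean.copy()
    var = state.prior_var.copy()
    mean[chosen] += kappa * delta
    var[chosen] *= 1.0 - kappa
    record = UpdateRecord(
        kalman_gain=kappa,
        prediction_error=delta,
        posterior_mean=mean[chosen],
        posterior_var=var[chosen],
    )
    return KalmanState(prior_mean=mean, prior_var=var), record


def kalman_drift(state: KalmanState, params: LearnerParams) -> KalmanState:
    """Between-trial drift of all bandits toward the estimated decay center."""
    lam, theta = params.est_lambda, params.est_center
    return KalmanState(
        prior_mean=lam * state.prior_mean + (1.0 - lam) * theta,
        prior_var=lam**2 * state.prior_var + params.est_diff_var,
    )


def delta_update(state: DeltaState, chosen: int, reward: float) -> DeltaState:
    """v_chosen <- v_chosen + alpha * (reward - v_chosen); others unchanged."""
    if not 0 <= chosen < state.value.size:
        raise IndexError(f"chosen bandit {chosen} out of range")
    if not math.isfinite(reward):
        raise ValueError(f"reward must be finite, got {reward!r}")
    value = state.value.copy()
    value[chosen] += state.learning_rate * (reward - value[chosen])
    return DeltaState(value=value, learning_rate=state.learning_rate)


@dataclass(frozen=True)
class Trajectory:
    """Per-trial pre-choice beliefs along one subject-condition sequence.

    ``mu_pre[t, i]`` / ``sigma_pre[t, i]`` are the prior mean and sd of bandit
    i at the moment of the trial-t choice (after the between-trial drift from
    trial t-1).  ``records[t]`` is the within-trial update for responded
    trials and None for missed trials.
    """

    mu_pre: np.ndarray
    sigma_pre: np.ndarray
    records: tuple[UpdateRecord | None, ...]

    @property
    def n_trials(self) -> int:
        return self.mu_pre.shape[0]

    @property
    def n_bandits(self) -> int:
        return self.mu_pre.shape[1]

    @property
    def sum_sigma_pre(self) -> np.ndarray:
        """Overall uncertainty per trial: sum of all bandits' prior sds."""
        return self.sigma_pre.sum(axis=1)


def run_learner(
    choices: np.ndarray,
    rewards: np.ndarray,
    responded: np.ndarray | None = None,
    params: LearnerParams = LearnerParams(),
    *,
    kind: str = "bayes",
    alpha: float | None = None,
    n_bandits: int = 4,
    v1: float = 50.0,
) -> Trajectory:
    """Run a learner over one subject-condition choice sequence.

    ``choices`` are 0-based bandit indices, ``rewards`` the observed points.
    Missed trials (``responded`` False) receive no within-trial update but the
    between-trial drift still applies.  For ``kind="delta"`` the mean follows
    the constant-``alpha`` Delta rule while the sd columns still follow the
    (reward-free) Kalman variance recursion so that uncertainty-bonus choice
    rules remain defined.

    Trial t's state reflects history through trial t-1 only.
    """
    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=float)
    n_trials = choices.size
    if responded is None:
        responded = np.ones(n_trials, dtype=bool)
    else:
        responded = np.asarray(responded, dtype=bool)
    if rewards.size != n_trials or responded.size != n_trials:
        raise ValueError("choices, rewards and responded must have equal length")
    if np.any(responded & ~np.isfinite(rewards)):
        raise ValueError("responded trials must carry a finite reward")
    if kind not in ("bayes", "delta"):
        raise ValueError(f"unknown learner kind {kind!r}")
    if kind == "delta" and alpha is None:
        raise ValueError("delta learner requires alpha")

    state = KalmanState.initial(params, n_bandits)
    dstate = DeltaState.initial(alpha, n_bandits, v1) if kind == "delta" else None

    mu_pre = np.empty((n_trials, n_bandits))
    sigma_pre = np.empty((n_trials, n_bandits))
    records: list[UpdateRecord | None] = []

    for t in range(n_trials):
        mu_pre[t] = dstate.value if kind == "delta" else state.prior_mean
        sigma_pre[t] = np.sqrt(state.prior_var)
        if responded[t]:
            state, rec = kalman_observe(state, choices[t], rewards[t], params)
            if kind == "delta":
                dstate = delta_update(dstate, choices[t], rewards[t])
                rec = UpdateRecord(
                    kalman_gain=dstate.learning_rate,
                    prediction_error=rewards[t] - mu_pre[t, choices[t]],
                    posterior_mean=dstate.value[choices[t]],
                    posterior_var=state.prior_var[choices[t]],
                )
            records.append(rec)
        else:
            records.append(None)
        state = kalman_drift(state, params)
        if kind == "delta":
            # Delta values do not decay between trials (no walk model).
            pass

    return Trajectory(mu_pre=mu_pre, sigma_pre=sigma_pre, records=tuple(records))
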
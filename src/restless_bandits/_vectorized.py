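"""Vectorized per-sequence likelihoods for the MCMC and optimization layers.

The Kalman learner's belief trajectory does not depend on any free choice
parameter (learner parameters are fixed), so each subject-condition sequence
can be reduced once to per-trial features; the likelihood of a whole batch of
candidate parameter vectors is then a single broadcasted softmax evaluation.
The Delta learner's mean trajectory depends on the free learning rate alpha
and is recomputed per batch with a vectorized recursion over trials.

These routines are checked against the scalar :func:`restless_bandits.choice.
log_likelihood` path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from restless_bandits.choice import MODEL_REGISTRY
from restless_bandits.learning import LearnerParams, run_learner

__all__ = ["SequenceFeatures", "sequence_features", "loglik_batch"]


@dataclass(frozen=True)
class SequenceFeatures:
    """Choice-parameter-independent features of one subject-condition sequence."""

    mu: np.ndarray  # (T, B) Kalman prior means
    sigma: np.ndarray  # (T, B) prior sds (shared by both learners)
    prev_ind: np.ndarray  # (T, B) indicator of the previous responded choice
    sum_sigma: np.ndarray  # (T,) total uncertainty
    choices: np.ndarray  # (T,) 0-based
    rewards: np.ndarray  # (T,)
    responded: np.ndarray  # (T,) bool

    @property
    def n_trials(self) -> int:
        return self.choices.size

    @property
    def n_responded(self) -> int:
        return int(self.responded.sum())


def sequence_features(
    choices: np.ndarray,
    rewards: np.ndarray,
    responded: np.ndarray | None = None,
    learner_params: LearnerParams = LearnerParams(),
    n_bandits: int = 4,
) -> SequenceFeatures:
    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=float)
    if responded is None:
        responded = np.ones(choices.size, dtype=bool)
    responded = np.asarray(responded, dtype=bool)

    traj = run_learner(
        choices, rewards, responded, learner_params, kind="bayes", n_bandits=n_bandits
    )
    prev_ind = np.zeros((choices.size, n_bandits))
    prev: int | None = None
    for t in range(choices.size):
        if prev is not None:
            prev_ind[t, prev] = 1.0
        if responded[t]:
            prev = int(choices[t])
    return SequenceFeatures(
        mu=traj.mu_pre,
        sigma=traj.sigma_pre,
        prev_ind=prev_ind,
        sum_sigma=traj.sum_sigma_pre,
        choices=choices,
        rewards=rewards,
        responded=responded,
    )


def _delta_means(feat: SequenceFeatures, alpha: np.ndarray, v1: float) -> np.ndarray:
    """Delta-rule mean trajectories for a batch of alphas: (K, T, B)."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    n_t, n_b = feat.mu.shape
    out = np.empty((alpha.size, n_t, n_b))
    v = np.full((alpha.size, n_b), v1)
    for t in range(n_t):
        out[:, t, :] = v
        if feat.responded[t]:
            c = feat.choices[t]
            v[:, c] += alpha * (feat.rewards[t] - v[:, c])
    return out


def loglik_batch(
    feat: SequenceFeatures,
    model: str,
    beta: np.ndarray,
    phi: np.ndarray | None = None,
    rho: np.ndarray | None = None,
    gamma: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    v1: float = 50.0,
) -> np.ndarray:
    """Log-likelihood of the sequence for K parameter vectors at once.

    All parameter arguments broadcast to shape (K,); the return is (K,).
    Parameters the model's rule does not use must be None.
    """
    spec = MODEL_REGISTRY[model]
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    k = beta.size

    if spec.learner == "delta":
        if alpha is None:
            raise ValueError("delta models require alpha")
        mu = _delta_means(feat, np.broadcast_to(alpha, (k,)), v1)  # (K, T, B)
    else:
        mu = feat.mu[None, :, :]  # (1, T, B)

    value = mu
    if spec.rule in ("sme", "smep", "smerp"):
        if phi is None:
            raise ValueError(f"rule {spec.rule!r} requires phi")
        value = value + np.reshape(phi, (-1, 1, 1)) * feat.sigma[None]
    if spec.rule in ("smep", "smerp"):
        if rho is None:
            raise ValueError(f"rule {spec.rule!r} requires rho")
        value = value + np.reshape(rho, (-1, 1, 1)) * feat.prev_ind[None]
    if spec.rule == "smerp":
        if gamma is None:
            raise ValueError("rule 'smerp' requires gamma")
        value = value + np.reshape(gamma, (-1, 1, 1)) * mu / feat.sum_sigma[None, :, None]

    logits = np.reshape(beta, (-1, 1, 1)) * value  # (K, T, B)
    lse = logsumexp(logits, axis=-1)  # (K, T)
    chosen = np.take_along_axis(
        logits, feat.choices[None, :, None], axis=2
    )[..., 0]  # (K, T)
    ll = ((chosen - lse) * feat.responded[None, :]).sum(axis=-1)
    return ll
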
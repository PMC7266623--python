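"""Restless four-armed bandit environment.

Each bandit's mean payoff follows a decaying Gaussian random walk

    mu[i, t+1] = lambda * mu[i, t] + (1 - lambda) * theta + v_t,
    v_t ~ N(0, sigma_d^2),

an AR(1) process with decay ``lambda`` toward center ``theta`` and diffusion
noise ``sigma_d``.  The realized payoff on a trial is the latent mean plus
observation noise, r ~ N(mu, sigma_o^2), displayed to the subject as a
non-negative integer point score.  Points convert to money at 5 cents per
100 points.
"""

from __future__ import annotations


import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WalkParams",
    "SessionConfig",
    "PayoffWalk",
    "generate_walk",
    "sample_payoff",
    "points_to_payout",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the decaying Gaussian random walk.

    Defaults are the task's generative values: decay 0.9836 toward center 50,
    observation sd 4 (sigma_o^2 = 16) and diffusion sd 2.8 (sigma_d^2 = 7.84).
    """

    decay_lambda: float = 0.9836
    decay_center: float = 50.0
    obs_sd: float = 4.0
    diff_sd: float = 2.8

    def __post_init__(self) -> None:
        for name in ("decay_lambda", "decay_center", "obs_sd", "diff_sd"):
            _require_finite(name, getattr(self, name))
        if not 0.0 < self.decay_lambda < 1.0:
            raise ValueError(
                f"decay_lambda must lie in (0, 1), got {self.decay_lambda}"
            )
        if self.obs_sd <= 0:
            raise ValueError(f"obs_sd must be > 0, got {self.obs_sd}")
        if self.diff_sd <= 0:
            raise ValueError(f"diff_sd must be > 0, got {self.diff_sd}")

    @property
    def stationary_sd(self) -> float:
        """Sd of the walk's stationary distribution, sqrt(sigma_d^2/(1-lambda^2))."""
        return self.diff_sd / math.sqrt(1.0 - self.decay_lambda**2)


@dataclass(frozen=True)
class SessionConfig:
    """Session structure: 300 trials in 4 blocks of 75, 4 bandits.

    ``cents_per_100_points`` encodes the payout rule (5 cents per 100 points).
    """

    n_trials: int = 300
    n_bandits: int = 4
    block_length: int = 75
    cents_per_100_points: float = 5.0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_bandits < 1 or self.block_length < 1:
            raise ValueError("counts must be >= 1")
        if self.n_trials % self.block_length != 0:
            raise ValueError(
                f"n_trials ({self.n_trials}) must be divisible by "
                f"block_length ({self.block_length})"
            )

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_length


@dataclass(frozen=True)
class PayoffWalk:
    """Realization of the environment: latent means and integer payoffs.

    Both arrays have shape (n_trials, n_bandits).  Latent means are continuous;
    payoffs are rounded to the nearest integer and floored at zero, matching
    the integer point display of the task.
    """

    latent_means: np.ndarray
    payoffs: np.ndarray

    def __post_init__(self) -> None:
        lm = np.asarray(self.latent_means, dtype=float)
        po = np.asarray(self.payoffs)
        if lm.ndim != 2 or po.shape != lm.shape:
            raise ValueError(
                f"latent_means and payoffs must share a 2-D shape, got "
                f"{lm.shape} vs {po.shape}"
            )
        if np.any(po < 0) or not np.issubdtype(po.dtype, np.integer):
            raise ValueError("payoffs must be non-negative integers")
        object.__setattr__(self, "latent_means", lm)
        object.__setattr__(self, "payoffs", po)

    @property
    def n_trials(self) -> int:
        return self.latent_means.shape[0]

    @property
    def n_bandits(self) -> int:
        return self.latent_means.shape[1]

    def best_bandit(self) -> np.ndarray:
        """Index of the bandit with the highest latent mean on each trial."""
        return np.argmax(self.latent_means, axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: trial (1-based), bandit (1-based), latent_mean, payoff."""
        t, b = np.meshgrid(
            np.arange(1, self.n_trials + 1),
            np.arange(1, self.n_bandits + 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "trial": t.ravel(),
                "bandit": b.ravel(),
                "latent_mean": self.latent_means.ravel(),
                "payoff": self.payoffs.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PayoffWalk":
        df = pd.read_csv(path, sep="\t")
        n_trials = int(df["trial"].max())
        n_bandits = int(df["bandit"].max())
        lm = np.full((n_trials, n_bandits), np.nan)
        po = np.zeros((n_trials, n_bandits), dtype=int)
        ti = df["trial"].to_numpy() - 1
        bi = df["bandit"].to_numpy() - 1
        lm[ti, bi] = df["latent_mean"].to_numpy()
        po[ti, bi] = df["payoff"].to_numpy()
        return cls(latent_means=lm, payoffs=po)


def generate_walk(
    params: WalkParams,
    config: SessionConfig = SessionConfig(),
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    init_means: np.ndarray | None = None,
) -> PayoffWalk:
    """Generate one payoff-walk realization for a session.

    A master ``seed`` derives three independent streams (initial means,
    diffusion noise, observation noise), so the same seed reproduces the walk
    bit-for-bit.  Initial latent means are drawn uniformly within two
    stationary standard deviations of the decay center unless ``init_means``
    is given explicitly.
    """
    if rng is None:
        if seed is None:
            raise ValueError("either seed or rng must be provided")
        streams = np.random.SeedSequence(seed).spawn(3)
        rng_init, rng_diff, rng_obs = (np.random.default_rng(s) for s in streams)
    else:
        rng_init = rng_diff = rng_obs = rng

    lam, theta = params.decay_lambda, params.decay_center
    n_t, n_b = config.n_trials, config.n_bandits

    if init_means is None:
        half_width = 2.0 * params.stationary_sd
        mu0 = rng_init.uniform(theta - half_width, theta + half_width, size=n_b)
    else:
        mu0 = np.asarray(init_means, dtype=float)
        if mu0.shape != (n_b,):
            raise ValueError(f"init_means must have shape ({n_b},)")

    means = np.empty((n_t, n_b))
    means[0] = mu0
    noise = rng_diff.normal(0.0, params.diff_sd, size=(n_t - 1, n_b))
    for t in range(1, n_t):
        means[t] = lam * means[t - 1] + (1.0 - lam) * theta + noise[t - 1]

    raw = means + rng_obs.normal(0.0, params.obs_sd, size=(n_t, n_b))
    payoffs = np.maximum(np.rint(raw).astype(int), 0)
    return PayoffWalk(latent_means=means, payoffs=payoffs)


def sample_payoff(walk: PayoffWalk, trial: int, bandit: int) -> int:
    """Realized payoff of ``bandit`` on ``trial`` (both 0-based)."""
    if not 0 <= trial < walk.n_trials:
        raise IndexError(f"trial {trial} out of range [0, {walk.n_trials})")
    if not 0 <= bandit < walk.n_bandits:
        raise IndexError(f"bandit {bandit} out of range [0, {walk.n_bandits})")
    return int(walk.payoffs[trial, bandit])


def points_to_payout(points: int, cents_per_100: float = 5.0) -> int:
    """Convert a point total to whole cents (5 cents per 100 points).

    Rounds half up, so 130 points -> 6.5 -> 7 cents.
    """
    if points < 0:
        raise ValueError(f"points must be >= 0, got {points}")
    exact = points * cents_per_100 / 100.0
    return int(math.floor(exact + 0.5))
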
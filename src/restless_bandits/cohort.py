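"""Synthetic cohorts: multi-subject, multi-condition choice data with known truth.

The generator emulates the study design: a within-subjects cohort (default
31 subjects) playing 300 trials of the restless four-armed bandit under three
conditions (placebo, ldopa, haloperidol).  Each condition has its own payoff
walk shared by all subjects; subject-level choice parameters are drawn from
condition-specific group normal distributions (mean M, sd Lambda) and choices
are simulated from one of the eight cognitive models.

:func:`emulate_study_effect` builds the default drug-effect scenario: the
group mean of the directed-exploration weight phi is reduced in the ldopa
condition only, mimicking the attenuation of directed exploration under
L-dopa, while all other group-level parameters stay identical across
conditions.  The default ground-truth means (M_beta=0.29, M_phi=1.34,
M_rho=4.11) are plausible single-subject posterior medians repurposed as
group means; they are synthetic choices, not fitted group estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from restless_bandits.choice import MODEL_REGISTRY, ChoiceParams, choice_probabilities
from restless_bandits.learning import (
    DeltaState,
    KalmanState,
    LearnerParams,
    delta_update,
    kalman_drift,
    kalman_observe,
)
from restless_bandits.task import PayoffWalk, SessionConfig, WalkParams, generate_walk

__all__ = [
    "CohortSpec",
    "SimulatedCohort",
    "draw_subject_params",
    "simulate_cohort",
    "emulate_study_effect",
]

#: supports used to truncate subject-level draws; parameters absent here are
#: unbounded (signed support)
_PARAM_SUPPORT = {"alpha": (0.0, 1.0), "beta": (0.0, np.inf)}

_DEFAULT_CONDITIONS = ("placebo", "ldopa", "haloperidol")
_DEFAULT_MEANS = {"beta": 0.29, "phi": 1.34, "rho": 4.11, "gamma": 0.0, "alpha": 0.3}
_DEFAULT_SDS = {"beta": 0.1, "phi": 0.5, "rho": 1.5, "gamma": 0.5, "alpha": 0.1}


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth population for a simulated cohort.

    ``group_means`` maps condition -> parameter -> M; ``group_sds`` maps
    parameter -> Lambda (shared across conditions).  All conditions share the
    same subject roster (within-subjects design).
    """

    n_subjects: int = 31
    conditions: tuple[str, ...] = _DEFAULT_CONDITIONS
    model: str = "bayes-smep"
    group_means: dict[str, dict[str, float]] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)
    omission_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.conditions) == 0:
            raise ValueError("at least one condition is required")
        if self.model not in MODEL_REGISTRY:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.omission_rate < 1.0:
            raise ValueError("omission_rate must lie in [0, 1)")
        free = MODEL_REGISTRY[self.model].free_params
        means = {
            cond: {
                p: self.group_means.get(cond, {}).get(p, _DEFAULT_MEANS[p])
                for p in free
            }
            for cond in self.conditions
        }
        sds = {p: self.group_sds.get(p, _DEFAULT_SDS[p]) for p in free}
        if any(s <= 0 for s in sds.values()):
            raise ValueError("group_sds must be > 0")
        object.__setattr__(self, "group_means", means)
        object.__setattr__(self, "group_sds", sds)

    @property
    def free_params(self) -> tuple[str, ...]:
        return MODEL_REGISTRY[self.model].free_params


def emulate_study_effect(
    base: CohortSpec | None = None,
    *,
    reduction: float = 0.5,
    condition: str = "ldopa",
) -> CohortSpec:
    """Spec with the group mean of phi scaled by (1 - reduction) in one condition.

    With ``reduction=0`` the conditions are exchangeable; with the default
    0.5 the target condition's directed-exploration weight is halved, an
    L-dopa-like attenuation.
    """
    base = base if base is not None else CohortSpec()
    if condition not in base.conditions:
        raise ValueError(f"condition {condition!r} not in spec")
    if "phi" not in base.free_params:
        raise ValueError(f"model {base.model!r} has no phi parameter")
    means = {c: dict(p) for c, p in base.group_means.items()}
    means[condition]["phi"] = means[condition]["phi"] * (1.0 - reduction)
    return replace(base, group_means=means)


def draw_subject_params(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Subject-level parameters ~ Normal(M, Lambda), truncated to support.

    Truncation (by resampling) applies only to parameters with a bounded
    support (beta >= 0, alpha in [0, 1]); signed parameters are untruncated.
    Returns a long DataFrame (subject, condition, parameter, value).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    rows = []
    for cond in spec.conditions:
        for param in spec.free_params:
            m = spec.group_means[cond][param]
            s = spec.group_sds[param]
            lo, hi = _PARAM_SUPPORT.get(param, (-np.inf, np.inf))
            draws = rng.normal(m, s, size=spec.n_subjects)
            for _ in range(1000):
                bad = (draws < lo) | (draws > hi)
                if not bad.any():
                    break
                draws[bad] = rng.normal(m, s, size=int(bad.sum()))
            else:
                draws = np.clip(draws, lo, hi)
            for subj in range(spec.n_subjects):
                rows.append(
                    {
                        "subject": subj + 1,
                        "condition": cond,
                        "parameter": param,
                        "value": draws[subj],
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulatedCohort:
    """Simulated choice data, ground truth and generating walks."""

    data: pd.DataFrame  # subject, condition, trial, choice, reward, responded
    truth: pd.DataFrame  # subject, condition, parameter, value
    walks: dict[str, PayoffWalk]
    spec: CohortSpec

    def sequence(self, subject: int, condition: str):
        """(choices, rewards, responded) arrays for one subject-condition, 0-based."""
        sl = self.data[
            (self.data["subject"] == subject) & (self.data["condition"] == condition)
        ].sort_values("trial")
        return (
            sl["choice"].to_numpy() - 1,
            sl["reward"].to_numpy(dtype=float),
            sl["responded"].to_numpy(dtype=bool),
        )

    def to_tsv(self, data_path, truth_path=None) -> None:
        self.data.to_csv(data_path, sep="\t", index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _simulate_sequence(
    walk: PayoffWalk,
    model: str,
    params: dict[str, float],
    learner_params: LearnerParams,
    omission_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    spec = MODEL_REGISTRY[model]
    n_t, n_b = walk.n_trials, walk.n_bandits
    state = KalmanState.initial(learner_params, n_b)
    dstate = (
        DeltaState.initial(params["alpha"], n_b) if spec.learner == "delta" else None
    )
    choices = np.zeros(n_t, dtype=int)
    rewards = np.full(n_t, np.nan)
    responded = np.ones(n_t, dtype=bool)
    prev: int | None = None
    for t in range(n_t):
        if omission_rate > 0 and rng.random() < omission_rate:
            responded[t] = False
            choices[t] = -1
        else:
            means = dstate.value if spec.learner == "delta" else state.prior_mean
            cp = ChoiceParams(
                beta=params["beta"],
                phi=params.get("phi"),
                rho=params.get("rho"),
                gamma=params.get("gamma"),
                previous_choice=prev,
            )
            p = choice_probabilities(spec.rule, means, np.sqrt(state.prior_var), cp)
            c = int(rng.choice(n_b, p=p))
            r = float(walk.payoffs[t, c])
            choices[t] = c
            rewards[t] = r
            state, _ = kalman_observe(state, c, r, learner_params)
            if dstate is not None:
                dstate = delta_update(dstate, c, r)
            prev = c
        state = kalman_drift(state, learner_params)
    return choices, rewards, responded


def simulate_cohort(
    spec: CohortSpec,
    walk_params: WalkParams = WalkParams(),
    session: SessionConfig = SessionConfig(),
    learner_params: LearnerParams = LearnerParams(),
) -> SimulatedCohort:
    """Simulate the full cohort described by ``spec``.

    One master seed derives independent streams for the per-condition walks,
    the subject-parameter draws and every subject-condition choice sequence.
    Each condition uses its own payoff walk, identical across subjects within
    a condition.
    """
    root = np.random.SeedSequence(spec.seed)
    walk_seeds, param_seed, choice_root = root.spawn(3)
    walks = {
        cond: generate_walk(
            walk_params, session, rng=np.random.default_rng(s)
        )
        for cond, s in zip(spec.conditions, walk_seeds.spawn(len(spec.conditions)))
    }
    truth = draw_subject_params(spec, np.random.default_rng(param_seed))
    truth_wide = truth.pivot_table(
        index=["subject", "condition"], columns="parameter", values="value"
    )

    choice_streams = iter(choice_root.spawn(spec.n_subjects * len(spec.conditions)))
    frames = []
    for subj in range(1, spec.n_subjects + 1):
        for cond in spec.conditions:
            rng = np.random.default_rng(next(choice_streams))
            params = truth_wide.loc[(subj, cond)].to_dict()
            choices, rewards, responded = _simulate_sequence(
                walks[cond], spec.model, params, learner_params,
                spec.omission_rate, rng,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "condition": cond,
                        "trial": np.arange(1, session.n_trials + 1),
                        "choice": choices + 1,
                        "reward": rewards,
                        "responded": responded,
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    return SimulatedCohort(data=data, truth=truth, walks=walks, spec=spec)


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format choice dataset TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "condition", "trial", "choice", "reward"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")
    if "responded" not in df.columns:
        df["responded"] = True
    return df
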
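"""Trial classification, model-free behavioral metrics and trial regressors.

A responded trial is *exploitation* when the chosen bandit has the highest
prior expected value mu_pre; otherwise it is *exploration*.  Exploration
trials split into *directed* exploration (the chosen bandit has the highest
prior uncertainty sigma_pre) and *random* exploration (any other bandit).
Exploitation takes precedence: a bandit that maximizes both value and
uncertainty counts as exploitation, and chosen-in-the-argmax-set resolves
ties (which arise at trial 1, when all beliefs are equal).

Model-free metrics mirror the standard task summaries: the percentage of
choices of the objectively best bandit (highest latent mean) per block, the
percentage of choice switches, and the monetary payout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from restless_bandits.choice import MODEL_REGISTRY, ChoiceParams, choice_probabilities
from restless_bandits.learning import LearnerParams, Trajectory, run_learner
from restless_bandits.task import PayoffWalk, points_to_payout

__all__ = [
    "classify_binary",
    "classify_trinary",
    "classify_trials",
    "compute_regressors",
    "export_regressors",
    "best_bandit_rate",
    "switch_rate",
    "BehavioralSummary",
    "behavioral_summary",
]

_TIE_TOL = 1e-12


def classify_binary(means: np.ndarray, chosen: int) -> str:
    """'exploit' iff the chosen bandit attains the maximum prior mean."""
    means = np.asarray(means, dtype=float)
    if means[chosen] >= means.max() - _TIE_TOL:
        return "exploit"
    return "explore"


def classify_trinary(means: np.ndarray, sds: np.ndarray, chosen: int) -> str:
    """Refine exploration into 'directed' (max-sigma chosen) vs 'random'."""
    if classify_binary(means, chosen) == "exploit":
        return "exploit"
    sds = np.asarray(sds, dtype=float)
    if sds[chosen] >= sds.max() - _TIE_TOL:
        return "directed"
    return "random"


def classify_trials(traj: Trajectory, choices: np.ndarray,
                    responded: np.ndarray | None = None) -> pd.DataFrame:
    """Binary and trinary class per trial; missed trials get class 'missed'."""
    choices = np.asarray(choices, dtype=int)
    if responded is None:
        responded = np.ones(choices.size, dtype=bool)
    binary, trinary = [], []
    for t in range(choices.size):
        if not responded[t]:
            binary.append("missed")
            trinary.append("missed")
            continue
        b = classify_binary(traj.mu_pre[t], choices[t])
        binary.append(b)
        trinary.append(
            "exploit" if b == "exploit"
            else classify_trinary(traj.mu_pre[t], traj.sigma_pre[t], choices[t])
        )
    return pd.DataFrame(
        {"trial": np.arange(1, choices.size + 1),
         "class_binary": binary, "class_trinary": trinary}
    )


def compute_regressors(
    choices: np.ndarray,
    rewards: np.ndarray,
    responded: np.ndarray | None = None,
    *,
    model: str = "bayes-smep",
    params: dict[str, float],
    learner_params: LearnerParams = LearnerParams(),
    n_bandits: int = 4,
) -> pd.DataFrame:
    """Trial-wise model-derived quantities for one subject-condition sequence.

    Columns: trial, mu_pre_chosen, sigma_pre_chosen, delta (prediction error),
    p_chosen (model choice probability), sum_sigma_pre (total uncertainty),
    persev_indicator, class_binary, class_trinary.  delta and p_chosen are NaN
    on missed trials.
    """
    spec = MODEL_REGISTRY[model]
    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=float)
    if responded is None:
        responded = np.ones(choices.size, dtype=bool)
    responded = np.asarray(responded, dtype=bool)

    traj = run_learner(
        choices, rewards, responded, learner_params,
        kind=spec.learner, alpha=params.get("alpha"), n_bandits=n_bandits,
    )
    classes = classify_trials(traj, choices, responded)

    n_t = choices.size
    mu_c = np.full(n_t, np.nan)
    sd_c = np.full(n_t, np.nan)
    delta = np.full(n_t, np.nan)
    p_c = np.full(n_t, np.nan)
    persev = np.zeros(n_t, dtype=int)
    prev: int | None = None
    for t in range(n_t):
        if not responded[t]:
            continue
        c = choices[t]
        mu_c[t] = traj.mu_pre[t, c]
        sd_c[t] = traj.sigma_pre[t, c]
        delta[t] = rewards[t] - mu_c[t]
        cp = ChoiceParams(
            beta=params["beta"], phi=params.get("phi"), rho=params.get("rho"),
            gamma=params.get("gamma"), previous_choice=prev,
        )
        p = choice_probabilities(spec.rule, traj.mu_pre[t], traj.sigma_pre[t], cp)
        p_c[t] = p[c]
        persev[t] = int(prev is not None and c == prev)
        prev = c
    out = pd.DataFrame(
        {
            "trial": np.arange(1, n_t + 1),
            "mu_pre_chosen": mu_c,
            "sigma_pre_chosen": sd_c,
            "delta": delta,
            "p_chosen": p_c,
            "sum_sigma_pre": traj.sum_sigma_pre,
            "persev_indicator": persev,
        }
    )
    return out.merge(classes, on="trial")


def export_regressors(regressors: pd.DataFrame, path) -> None:
    """Write a regressor table as TSV (round-trippable at float precision)."""
    regressors.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _block_edges(n_trials: int) -> list[tuple[str, int, int]]:
    """Task block scheme: trials 1-10, 11-50, then 50-trial blocks."""
    edges: list[tuple[str, int, int]] = [("trials_1_10", 1, min(10, n_trials))]
    if n_trials > 10:
        edges.append(("trials_11_50", 11, min(50, n_trials)))
    start = 51
    while start <= n_trials:
        stop = min(start + 49, n_trials)
        edges.append((f"trials_{start}_{stop}", start, stop))
        start = stop + 1
    return edges


def best_bandit_rate(
    choices: np.ndarray,
    walk: PayoffWalk,
    responded: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percent choices of the objectively best bandit, overall and per block.

    'Best' is the bandit with the highest latent mean on each trial.  Missed
    trials are excluded from denominators.  Returns rows (block, percent, n).
    """
    choices = np.asarray(choices, dtype=int)
    if responded is None:
        responded = np.ones(choices.size, dtype=bool)
    responded = np.asarray(responded, dtype=bool)
    best = walk.best_bandit()[: choices.size]
    hit = (choices == best) & responded
    rows = [{
        "block": "overall",
        "percent": 100.0 * hit.sum() / max(responded.sum(), 1),
        "n": int(responded.sum()),
    }]
    for label, start, stop in _block_edges(choices.size):
        sl = slice(start - 1, stop)
        n = int(responded[sl].sum())
        pct = 100.0 * hit[sl].sum() / n if n else np.nan
        rows.append({"block": label, "percent": pct, "n": n})
    return pd.DataFrame(rows)


def switch_rate(choices: np.ndarray, responded: np.ndarray | None = None) -> float:
    """Percent of responded trials whose choice differs from the previous one.

    The denominator counts responded trials from the second responded trial
    on; comparisons skip missed trials.
    """
    choices = np.asarray(choices, dtype=int)
    if responded is None:
        responded = np.ones(choices.size, dtype=bool)
    seq = choices[np.asarray(responded, dtype=bool)]
    if seq.size < 2:
        raise ValueError("switch_rate requires at least two responded trials")
    return 100.0 * float(np.mean(seq[1:] != seq[:-1]))


@dataclass(frozen=True)
class BehavioralSummary:
    """Model-free and classification summaries for one subject-condition."""

    percent_best_bandit: pd.DataFrame  # block, percent, n
    percent_switches: float
    total_points: int
    payout_cents: int
    class_percent: pd.DataFrame  # block, exploit, directed, random (percent)


def behavioral_summary(
    choices: np.ndarray,
    rewards: np.ndarray,
    walk: PayoffWalk,
    responded: np.ndarray | None = None,
    *,
    params: dict[str, float] | None = None,
    model: str = "bayes-smep",
    learner_params: LearnerParams = LearnerParams(),
    class_block: int = 50,
    include_trial_1: bool = False,
) -> BehavioralSummary:
    """Full behavioral summary; classification needs model ``params``.

    Trial 1 is excluded from the classification percentages by default (all
    beliefs are equal there, so it is exploitation by the tie rule).
    """
    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=float)
    if responded is None:
        responded = np.ones(choices.size, dtype=bool)
    responded = np.asarray(responded, dtype=bool)

    total_points = int(np.nansum(np.where(responded, rewards, 0.0)))
    if params is None:
        raise ValueError("behavioral_summary requires model params")
    regs = compute_regressors(
        choices, rewards, responded, model=model, params=params,
        learner_params=learner_params,
    )
    tri = regs["class_trinary"].to_numpy()
    valid = responded.copy()
    if not include_trial_1:
        valid[0] = False

    rows = []
    n_t = choices.size
    for start in range(0, n_t, class_block):
        sl = slice(start, min(start + class_block, n_t))
        mask = valid[sl]
        n = int(mask.sum())
        row = {"block": f"trials_{start + 1}_{min(start + class_block, n_t)}"}
        for label in ("exploit", "directed", "random"):
            row[label] = (
                100.0 * float(np.sum((tri[sl] == label) & mask)) / n if n else np.nan
            )
        row["n"] = n
        rows.append(row)
    overall = {"block": "overall", "n": int(valid.sum())}
    for label in ("exploit", "directed", "random"):
        overall[label] = 100.0 * float(np.sum((tri == label) & valid)) / max(valid.sum(), 1)
    rows.append(overall)

    return BehavioralSummary(
        percent_best_bandit=best_bandit_rate(choices, walk, responded),
        percent_switches=switch_rate(choices, responded),
        total_points=total_points,
        payout_cents=points_to_payout(total_points),
        class_percent=pd.DataFrame(rows),
    )
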
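"""End-to-end pipeline: simulate -> fit -> compare -> classify -> report.

Every run writes a deterministic artifact tree under its output directory:

    resolved_config.yaml   exact configuration after defaults
    seed_manifest.json     master seed and derived stage seeds
    dataset.tsv            simulated or copied input data
    truth.tsv              ground-truth parameters (simulated runs)
    walk_<condition>.tsv   payoff walks (simulated runs)
    fits/<model>/          posterior draws, diagnostics, subject medians
    loo_comparison.tsv     model ranking (when >1 model is fitted)
    regressors/            trial-wise regressor TSVs per subject-condition
    behavior_summary.tsv   model-free + classification summaries
    run.log                structured per-stage log
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from restless_bandits.choice import MODEL_REGISTRY, list_models
from restless_bandits.cohort import (
    CohortSpec,
    SimulatedCohort,
    emulate_study_effect,
    read_dataset,
    simulate_cohort,
)
from restless_bandits.comparison import compare_models, pointwise_loglik, psis_loo
from restless_bandits.inference import (
    CI_SAMPLER,
    PriorSpec,
    SamplerConfig,
    fit_hierarchical,
)
from restless_bandits.metrics import (
    behavioral_summary,
    compute_regressors,
    export_regressors,
    switch_rate,
)
from restless_bandits.task import SessionConfig, WalkParams

__all__ = ["RunConfig", "ValidationReport", "run_pipeline", "validate_dataset"]

log = logging.getLogger("restless_bandits.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    dataset: str = "simulate"  # 'simulate' or a TSV path
    model: str = "bayes-smep"  # a model name or 'all8'
    profile: str = "ci"  # 'ci' or 'full'
    n_subjects: int = 8
    conditions: tuple[str, ...] = ("placebo", "ldopa", "haloperidol")
    phi_reduction: float = 0.5
    omission_rate: float = 0.0
    n_trials: int = 300
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model != "all8" and self.model not in MODEL_REGISTRY:
            raise ValueError(f"model: unknown value {self.model!r}")
        if self.profile not in ("ci", "full"):
            raise ValueError(f"profile: must be 'ci' or 'full', got {self.profile!r}")
        if self.dataset != "simulate" and not Path(self.dataset).exists():
            raise ValueError(f"dataset: file not found: {self.dataset}")
        if not 0.0 <= self.phi_reduction < 1.0:
            raise ValueError("phi_reduction: must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def models(self) -> list[str]:
        return list_models() if self.model == "all8" else [self.model]

    def sampler(self, seed: int) -> SamplerConfig:
        base = CI_SAMPLER if self.profile == "ci" else SamplerConfig()
        return SamplerConfig(
            n_chains=base.n_chains,
            n_warmup=base.n_warmup,
            n_samples=base.n_samples,
            seed=seed,
        )


@dataclass(frozen=True)
class ValidationReport:
    """Schema and consistency violations found in a dataset file."""

    violations: tuple[dict, ...]

    @property
    def ok(self) -> bool:
        return len(self.violations) == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.violations))


def validate_dataset(path, n_bandits: int = 4) -> ValidationReport:
    """Check schema, trial monotonicity, choice range and reward integrality."""
    violations: list[dict] = []
    try:
        df = read_dataset(path)
    except ValueError as err:
        return ValidationReport(violations=({"row": None, "problem": str(err)},))
    responded = df["responded"].astype(bool)
    bad_choice = responded & ~df["choice"].isin(range(1, n_bandits + 1))
    for idx in df.index[bad_choice]:
        violations.append(
            {"row": int(idx), "problem": f"choice {df.loc[idx, 'choice']} outside 1..{n_bandits}"}
        )
    rewards = df.loc[responded, "reward"]
    bad_reward = rewards.notna() & (rewards != rewards.round())
    for idx in rewards.index[bad_reward]:
        violations.append(
            {"row": int(idx), "problem": f"non-integer reward {df.loc[idx, 'reward']}"}
        )
    missing_reward = df.loc[responded, "reward"].isna()
    for idx in missing_reward.index[missing_reward]:
        violations.append({"row": int(idx), "problem": "responded trial without reward"})
    for (subj, cond), grp in df.groupby(["subject", "condition"]):
        trials = grp["trial"].to_numpy()
        if np.any(np.diff(trials) <= 0):
            violations.append(
                {
                    "row": int(grp.index[0]),
                    "problem": f"non-monotone trial order for subject {subj}, "
                    f"condition {cond}",
                }
            )
    return ValidationReport(violations=tuple(violations))


def _setup_logging(out_dir: Path, level: str) -> None:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    root = logging.getLogger("restless_bandits")
    root.setLevel(level)
    root.addHandler(handler)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the pipeline described by ``config``; returns the run directory.

    Raises RuntimeError at the end if any fit failed the hard convergence
    threshold, after all artifacts are written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)

    root_seq = np.random.SeedSequence(config.seed)
    sim_seed, fit_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in root_seq.spawn(2)
    )
    manifest = {"master_seed": config.seed, "simulate_seed": sim_seed,
                "fit_seed": fit_seed}
    with open(out / "seed_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(config).items()},
            fh,
        )

    session = SessionConfig(n_trials=config.n_trials)
    cohort: SimulatedCohort | None = None
    t0 = time.perf_counter()
    if config.dataset == "simulate":
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            conditions=config.conditions,
            omission_rate=config.omission_rate,
            seed=sim_seed,
        )
        if config.phi_reduction > 0 and "ldopa" in config.conditions:
            spec = emulate_study_effect(spec, reduction=config.phi_reduction)
        cohort = simulate_cohort(spec, WalkParams(), session)
        cohort.to_tsv(out / "dataset.tsv", out / "truth.tsv")
        for cond, walk in cohort.walks.items():
            walk.to_tsv(out / f"walk_{cond}.tsv")
        data = cohort.data
        log.info("simulate: %d subjects x %d conditions in %.1fs",
                 spec.n_subjects, len(spec.conditions), time.perf_counter() - t0)
    else:
        data = read_dataset(config.dataset)
        data.to_csv(out / "dataset.tsv", sep="\t", index=False)
        log.info("loaded dataset %s", config.dataset)

    report = validate_dataset(out / "dataset.tsv")
    if not report.ok:
        report.to_frame().to_csv(out / "validation.tsv", sep="\t", index=False)
        raise RuntimeError(f"dataset failed validation: {len(report.violations)} problems")

    fits = {}
    for model in config.models():
        t0 = time.perf_counter()
        fit = fit_hierarchical(
            data, model=model, priors=PriorSpec(),
            sampler=config.sampler(fit_seed),
        )
        fits[model] = fit
        fit.to_tsv(out / "fits" / model)
        log.info("fit %s: converged=%s in %.1fs", model, fit.converged,
                 time.perf_counter() - t0)

    best_model = config.models()[0]
    if len(fits) > 1:
        loo = {m: psis_loo(pointwise_loglik(f)) for m, f in fits.items()}
        table = compare_models(loo)
        table.to_csv(out / "loo_comparison.tsv", sep="\t", index=False)
        best_model = str(table.iloc[0]["model"])
        log.info("compare: best model %s", best_model)

    best_fit = fits[best_model]
    medians = best_fit.subject_medians().pivot_table(
        index=["subject", "condition"], columns="parameter", values="value"
    )
    reg_dir = out / "regressors"
    reg_dir.mkdir(exist_ok=True)
    rows = []
    for (subj, cond), params in medians.iterrows():
        sl = data[(data["subject"] == subj) & (data["condition"] == cond)].sort_values(
            "trial"
        )
        choices = sl["choice"].to_numpy(dtype=int) - 1
        rewards = sl["reward"].to_numpy(dtype=float)
        responded = sl["responded"].to_numpy(dtype=bool)
        regs = compute_regressors(
            choices, rewards, responded, model=best_model, params=params.to_dict()
        )
        export_regressors(regs, reg_dir / f"sub{subj:02d}_{cond}.tsv")
        row = {"subject": subj, "condition": cond,
               "percent_switches": switch_rate(choices, responded)}
        if cohort is not None:
            summ = behavioral_summary(
                choices, rewards, cohort.walks[cond], responded,
                params=params.to_dict(), model=best_model,
            )
            row["percent_best_bandit"] = float(
                summ.percent_best_bandit.loc[
                    summ.percent_best_bandit["block"] == "overall", "percent"
                ].iloc[0]
            )
            row["payout_cents"] = summ.payout_cents
            overall = summ.class_percent[summ.class_percent["block"] == "overall"]
            for label in ("exploit", "directed", "random"):
                row[f"percent_{label}"] = float(overall[label].iloc[0])
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "behavior_summary.tsv", sep="\t", index=False)
    log.info("classify: wrote %d regressor files", len(rows))

    if not all(f.converged for f in fits.values()):
        bad = [m for m, f in fits.items() if not f.converged]
        raise RuntimeError(f"fits failed convergence threshold: {bad}")
    return out
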
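"""Model comparison by PSIS-LOO with subject-by-condition pointwise structure.

One held-out unit is the data of one subject under one condition, compounded
over trials.  For each unit the leave-one-out expected log predictive density
is approximated from the full-data posterior draws by Pareto-smoothed
importance sampling: raw importance ratios 1/p(y_unit | theta_draw) are
tail-smoothed with a generalized-Pareto fit (largest 20% of ratios), and

    elpd_loo(unit) = log( sum_d w_d * p(y_unit | theta_d) )

with normalized smoothed weights w.  Units with a Pareto shape k > 0.7 are
flagged as unreliable.  Totals are also reported per data point (divided by
the summed trial counts) for comparability across datasets; the relative
order of models is invariant to that linear rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from restless_bandits.inference import PosteriorFit

__all__ = [
    "PointwiseLogLik",
    "LooResult",
    "pointwise_loglik",
    "psis_loo",
    "compare_models",
]

_PARETO_K_WARN = 0.7


@dataclass(frozen=True)
class PointwiseLogLik:
    """Log-likelihood draws per unit (subject x condition).

    ``matrix`` has shape (n_draws, n_units); column ``j`` holds the total
    log-likelihood of unit ``j``'s trials at each posterior draw of the fit
    that produced it.  ``n_trials`` holds responded-trial counts per unit.
    """

    matrix: np.ndarray
    units: tuple[tuple[int, str], ...]  # (subject, condition)
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.units):
            raise ValueError("matrix must be (n_draws, n_units)")
        if not np.all(np.isfinite(m)):
            raise ValueError("pointwise log-likelihoods must be finite")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "n_trials", np.asarray(self.n_trials, dtype=int)
        )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_data_points(self) -> int:
        return int(self.n_trials.sum())


def pointwise_loglik(
    fit: PosteriorFit, conditions: tuple[str, ...] | None = None
) -> PointwiseLogLik:
    """Extract the pointwise log-likelihood matrix from a hierarchical fit.

    Conditions are fitted independently, so each unit's column comes from its
    own condition's posterior draws; draw counts match across conditions by
    the shared sampler configuration.
    """
    conditions = conditions or fit.conditions
    blocks, units, n_trials = [], [], []
    for cond in conditions:
        ll = fit.pointwise(cond)  # (n_draws, n_subjects)
        blocks.append(ll)
        units.extend((subj, cond) for subj in fit.subjects[cond])
        n_trials.extend(fit.n_trials_per_unit[cond])
    n_draws = {b.shape[0] for b in blocks}
    if len(n_draws) != 1:
        raise ValueError("conditions carry unequal draw counts")
    return PointwiseLogLik(
        matrix=np.concatenate(blocks, axis=1),
        units=tuple(units),
        n_trials=np.array(n_trials),
    )


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO estimate for one model on one dataset."""

    elpd_total: float
    elpd_per_unit: np.ndarray
    pareto_k: np.ndarray
    normalized: float  # per data point
    se: float
    n_units: int
    n_data_points: int
    units: tuple[tuple[int, str], ...]
    degenerate: bool = False


def psis_loo(pll: PointwiseLogLik, reff: float = 1.0) -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood matrix.

    A posterior with (numerically) zero variance in the likelihood draws has
    uniform importance weights; LOO then equals the plain log-likelihood and
    the result is flagged ``degenerate`` with a warning.
    """
    ll = pll.matrix
    if ll.shape[0] < 2:
        raise ValueError("psis_loo requires at least 2 draws")
    spread = ll.max(axis=0) - ll.min(axis=0)
    degenerate = bool(np.all(spread < 1e-10))
    if degenerate:
        warnings.warn(
            "posterior draws are identical; importance weights are degenerate "
            "and LOO equals the in-sample log-likelihood",
            RuntimeWarning,
            stacklevel=2,
        )
        elpd = ll[0].copy()
        k = np.zeros(pll.n_units)
    else:
        # arviz expects samples on the last axis
        lw, k = az.psislw(-ll.T, reff=reff)
        elpd = logsumexp(lw + ll.T, axis=1)
        k = np.asarray(k, dtype=float)
    if np.any(k > _PARETO_K_WARN):
        warnings.warn(
            f"{int(np.sum(k > _PARETO_K_WARN))} unit(s) with Pareto k > "
            f"{_PARETO_K_WARN}; LOO may be unreliable for them",
            RuntimeWarning,
            stacklevel=2,
        )
    total = float(elpd.sum())
    se = float(np.std(elpd, ddof=1) * np.sqrt(pll.n_units)) if pll.n_units > 1 else 0.0
    return LooResult(
        elpd_total=total,
        elpd_per_unit=np.asarray(elpd, dtype=float),
        pareto_k=k,
        normalized=total / pll.n_data_points,
        se=se,
        n_units=pll.n_units,
        n_data_points=pll.n_data_points,
        units=pll.units,
        degenerate=degenerate,
    )


def compare_models(results: dict[str, LooResult]) -> pd.DataFrame:
    """Rank models by LOO; pairwise differences use per-unit contributions.

    All results must cover identical units.  Returns a DataFrame sorted best
    first with columns model, loo_total, loo_normalized, se, delta_to_best,
    se_delta, worst_pareto_k.
    """
    if len(results) < 1:
        raise ValueError("need at least one model")
    units_sets = {tuple(r.units) for r in results.values()}
    if len(units_sets) != 1:
        raise ValueError("models were evaluated on different units")
    best_name = max(results, key=lambda n: results[n].elpd_total)
    best = results[best_name]
    rows = []
    for name, r in results.items():
        diff = best.elpd_per_unit - r.elpd_per_unit
        se_delta = (
            float(np.std(diff, ddof=1) * np.sqrt(r.n_units))
            if r.n_units > 1 and name != best_name
            else 0.0
        )
        rows.append(
            {
                "model": name,
                "loo_total": r.elpd_total,
                "loo_normalized": r.normalized,
                "se": r.se,
                "delta_to_best": best.elpd_total - r.elpd_total,
                "se_delta": se_delta,
                "worst_pareto_k": float(r.pareto_k.max()) if r.pareto_k.size else 0.0,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("loo_total", ascending=False)
        .reset_index(drop=True)
    )
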
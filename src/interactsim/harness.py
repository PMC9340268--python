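"""Replication harness: run R simulated studies per scenario and summarize.

Each replication draws one cohort, fits the logistic interaction model
(always) and the boosted-tree + SHAP estimator (in full mode), and
records both pairs of stratum odds ratios together with the Wald test of
the product term.  Scenario-level summaries report:

* power — fraction of replications with Wald p below alpha;
* sign sensitivity — fraction in which the estimated diet odds ratio is
  more protective among women than among men (OR_W < OR_M; ties fail);
* bias — mean estimated interaction coefficient minus ln(or_w / or_m);
* 2.5th / 50th / 97.5th percentiles of the per-sex odds-ratio sampling
  distributions.

Direction convention: the "correct" ordering of a genuine protective
interaction is a *smaller* (more protective) odds ratio among women.
In prose this is often phrased as the diet benefit being "greater among
women"; numerically it is OR_W < OR_M, and that inequality is what the
sign-sensitivity fraction counts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .boosted import BoostParams, DEFAULT_GRID, compute_shap, shap_based_ors, train_boosted, tune_hyperparameters
from .cohort import (
    Cohort,
    CovariateModel,
    DEFAULT_COHORT_SIZE,
    Scenario,
    generate_cohort,
    replication_seed,
)
from .logistic import INTERACTION_TERM, fit_logistic, logistic_ors, wald_interaction_test

__all__ = [
    "HarnessConfig",
    "ReplicationResult",
    "StudySummary",
    "run_replication",
    "run_scenario",
    "run_study",
    "power",
    "sign_sensitivity",
    "bias",
    "summarize_study",
    "results_to_frame",
    "results_from_frame",
]


@dataclass(frozen=True)
class HarnessConfig:
    """Run-time options shared by all replications of a study.

    ``mode="fast"`` runs only the logistic estimator; ``mode="full"``
    additionally trains the boosted model and computes SHAP odds ratios
    per replication.  In full mode hyperparameters are tuned once per
    scenario on replication 0's cohort and reused, unless
    ``tune_per_replication`` is set or ``boost_params`` pins them.
    """

    n: int = DEFAULT_COHORT_SIZE
    alpha: float = 0.05
    mode: str = "fast"
    boost_params: BoostParams | None = None
    boost_grid: tuple[BoostParams, ...] = DEFAULT_GRID
    tune_folds: int = 2
    tune_per_replication: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("fast", "full"):
            raise ValueError("mode must be 'fast' or 'full'")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class ReplicationResult:
    """Estimates from one simulated study."""

    scenario_name: str
    rep: int
    seed: int
    converged: bool
    l_or_m: float = math.nan
    l_or_w: float = math.nan
    b_int_hat: float = math.nan
    se_int: float = math.nan
    z: float = math.nan
    p: float = math.nan
    s_or_m: float = math.nan
    s_or_w: float = math.nan


@dataclass(frozen=True)
class StudySummary:
    """Scenario-level metrics over converged replications."""

    scenario_name: str
    n_reps: int
    n_excluded: int
    power: float
    sign_sens_lr: float
    sign_sens_shap: float | None
    bias: float
    # (2.5th, 50th, 97.5th) percentiles of the logistic stratum ORs
    or_m_pct: tuple[float, float, float]
    or_w_pct: tuple[float, float, float]


def _tuned_params(
    model: CovariateModel,
    scenario: Scenario,
    base_seed: int,
    config: HarnessConfig,
) -> BoostParams:
    seed = replication_seed(base_seed, scenario.name, 0)
    cohort = generate_cohort(model, scenario, n=config.n, seed=seed)
    return tune_hyperparameters(
        cohort, grid=config.boost_grid, folds=config.tune_folds, seed=seed
    )


def run_replication(
    model: CovariateModel,
    scenario: Scenario,
    rep: int,
    base_seed: int,
    config: HarnessConfig = HarnessConfig(),
    boost_params: BoostParams | None = None,
) -> ReplicationResult:
    """One simulated study, fully reproducible from (base_seed, scenario, rep)."""
    seed = replication_seed(base_seed, scenario.name, rep)
    cohort = generate_cohort(model, scenario, n=config.n, seed=seed)
    fit = fit_logistic(cohort)
    if not fit.converged:
        return ReplicationResult(
            scenario_name=scenario.name, rep=rep, seed=seed, converged=False
        )
    ors = logistic_ors(fit)
    wald = wald_interaction_test(fit)
    result = ReplicationResult(
        scenario_name=scenario.name,
        rep=rep,
        seed=seed,
        converged=True,
        l_or_m=ors.or_m_hat,
        l_or_w=ors.or_w_hat,
        b_int_hat=float(fit.params[INTERACTION_TERM]),
        se_int=fit.se(INTERACTION_TERM),
        z=wald.z,
        p=wald.p,
    )
    if config.mode == "full":
        params = boost_params or config.boost_params
        if params is None:
            if not config.tune_per_replication:
                raise ValueError(
                    "full mode without boost_params requires tuning; pass "
                    "boost_params or enable tune_per_replication (run_scenario "
                    "tunes once per scenario automatically)"
                )
            params = tune_hyperparameters(
                cohort, grid=config.boost_grid, folds=config.tune_folds, seed=seed
            )
        booster = train_boosted(cohort, params, seed=seed)
        shap = compute_shap(booster, cohort)
        s_ors = shap_based_ors(shap, cohort)
        result = dataclasses.replace(
            result, s_or_m=s_ors.or_m_hat, s_or_w=s_ors.or_w_hat
        )
    return result


def run_scenario(
    model: CovariateModel,
    scenario: Scenario,
    reps: int,
    base_seed: int,
    config: HarnessConfig = HarnessConfig(),
    progress: Callable[[str], None] | None = None,
) -> list[ReplicationResult]:
    """All replications of one scenario.

    In full mode without pinned ``boost_params``, hyperparameters are
    tuned once on replication 0's cohort and reused for every
    replication of the scenario.
    """
    boost_params = config.boost_params
    if (
        config.mode == "full"
        and boost_params is None
        and not config.tune_per_replication
    ):
        boost_params = _tuned_params(model, scenario, base_seed, config)
        if progress is not None:
            progress(f"{scenario.name}: tuned {boost_params}")
    results = []
    for rep in range(reps):
        results.append(
            run_replication(
                model, scenario, rep, base_seed, config, boost_params=boost_params
            )
        )
        if progress is not None and (rep + 1) % 50 == 0:
            progress(f"{scenario.name}: {rep + 1}/{reps} replications")
    excluded = sum(not r.converged for r in results)
    if progress is not None and excluded:
        progress(f"{scenario.name}: excluded {excluded} non-converged replications")
    return results


def _converged(results: Iterable[ReplicationResult]) -> list[ReplicationResult]:
    kept = [r for r in results if r.converged]
    if not kept:
        raise ValueError("no converged replications")
    return kept


def power(results: Iterable[ReplicationResult], alpha: float = 0.05) -> float:
    """Fraction of converged replications rejecting the no-interaction test."""
    kept = _converged(results)
    return sum(r.p < alpha for r in kept) / len(kept)


def sign_sensitivity(
    results: Iterable[ReplicationResult], source: str = "logistic"
) -> float:
    """Fraction of replications estimating OR_W strictly below OR_M.

    Ties (possible for tree-based odds ratios) count as failures — a tie
    is not evidence of the correct ordering.
    """
    kept = _converged(results)
    if source == "logistic":
        pairs = [(r.l_or_w, r.l_or_m) for r in kept]
    elif source == "shap":
        pairs = [(r.s_or_w, r.s_or_m) for r in kept]
        if any(math.isnan(w) or math.isnan(m) for w, m in pairs):
            raise ValueError("SHAP odds ratios missing (fast-mode results?)")
    else:
        raise ValueError(f"unknown source {source!r}")
    return sum(w < m for w, m in pairs) / len(pairs)


def bias(results: Iterable[ReplicationResult], scenario: Scenario) -> float:
    """Mean estimated interaction coefficient minus its true value."""
    kept = _converged(results)
    return float(
        np.mean([r.b_int_hat for r in kept]) - scenario.beta_interaction
    )


def summarize_study(
    results: Sequence[ReplicationResult],
    scenario: Scenario,
    alpha: float = 0.05,
) -> StudySummary:
    """Assemble all scenario metrics, including OR sampling percentiles."""
    kept = _converged(results)
    if len(kept) < 2:
        raise ValueError("need at least 2 converged replications to summarize")
    or_m = np.array([r.l_or_m for r in kept])
    or_w = np.array([r.l_or_w for r in kept])
    has_shap = all(not math.isnan(r.s_or_w) for r in kept)
    q = (2.5, 50.0, 97.5)
    return StudySummary(
        scenario_name=scenario.name,
        n_reps=len(kept),
        n_excluded=len(results) - len(kept),
        power=power(kept, alpha),
        sign_sens_lr=sign_sensitivity(kept, "logistic"),
        sign_sens_shap=sign_sensitivity(kept, "shap") if has_shap else None,
        bias=bias(kept, scenario),
        or_m_pct=tuple(np.percentile(or_m, q)),
        or_w_pct=tuple(np.percentile(or_w, q)),
    )


def run_study(
    model_for: Callable[[Scenario], CovariateModel] | CovariateModel,
    scenarios: Sequence[Scenario],
    reps: int,
    base_seed: int,
    config: HarnessConfig = HarnessConfig(),
    progress: Callable[[str], None] | None = None,
) -> tuple[dict[str, list[ReplicationResult]], list[StudySummary]]:
    """Run every scenario and summarize each.

    ``model_for`` may be a single calibrated model or a callable mapping
    each scenario to its own calibrated model (the intercept calibration
    depends slightly on the scenario's diet effect).
    """
    results: dict[str, list[ReplicationResult]] = {}
    summaries: list[StudySummary] = []
    for scenario in scenarios:
        model = model_for(scenario) if callable(model_for) else model_for
        res = run_scenario(model, scenario, reps, base_seed, config, progress)
        results[scenario.name] = res
        summaries.append(summarize_study(res, scenario, config.alpha))
    return results, summaries


# ---------------------------------------------------------------------------
# CSV round-trip for replication-level records

_BOOL_COLS = ("converged",)
_INT_COLS = ("rep", "seed")


def results_to_frame(results: Iterable[ReplicationResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def results_from_frame(frame: pd.DataFrame) -> list[ReplicationResult]:
    out = []
    for row in frame.to_dict(orient="records"):
        for c in _INT_COLS:
            row[c] = int(row[c])
        for c in _BOOL_COLS:
            row[c] = bool(row[c])
        out.append(ReplicationResult(**row))
    return out


def save_results(results: Iterable[ReplicationResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def load_results(path) -> list[ReplicationResult]:
    # round_trip parsing keeps the shortest-repr floats written by to_csv exact
    return results_from_frame(pd.read_csv(path, float_precision="round_trip"))


def summaries_to_frame(summaries: Iterable[StudySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dataclasses.asdict(s)
        for sex in ("m", "w"):
            p = row.pop(f"or_{sex}_pct")
            row[f"or_{sex}_pct_2_5"], row[f"or_{sex}_pct_50"], row[f"or_{sex}_pct_97_5"] = p
        rows.append(row)
    return pd.DataFrame(rows)
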
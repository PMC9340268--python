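"""Figures: odds-ratio sampling distributions and SHAP dependence plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "interactsim"

import matplotlib.pyplot as plt
import numpy as np

from .boosted import ShapMatrix
from .cohort import Cohort
from .harness import ReplicationResult, StudySummary

__all__ = ["or_sampling_histogram", "shap_dependence_plot"]

#: Fixed bin count on the log-OR axis so panels are comparable.
N_BINS = 40

_MEN_COLOR = "#2166ac"
_WOMEN_COLOR = "#b2182b"


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def or_sampling_histogram(
    results: Sequence[ReplicationResult],
    summary: StudySummary,
    path: str | Path,
    source: str = "logistic",
) -> None:
    """Histogram of ln(OR) per sex across replications, with the 2.5th,
    50th and 97.5th percentile annotations of the odds-ratio sampling
    distribution."""
    kept = [r for r in results if r.converged]
    if source == "logistic":
        or_m = np.array([r.l_or_m for r in kept])
        or_w = np.array([r.l_or_w for r in kept])
        label = "L-OR"
    elif source == "shap":
        or_m = np.array([r.s_or_m for r in kept])
        or_w = np.array([r.s_or_w for r in kept])
        label = "S-OR"
    else:
        raise ValueError(f"unknown source {source!r}")
    log_all = np.log(np.concatenate([or_m, or_w]))
    bins = np.linspace(log_all.min(), log_all.max(), N_BINS + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(np.log(or_m), bins=bins, alpha=0.6, color=_MEN_COLOR,
            label=f"men ({label}$_M$)")
    ax.hist(np.log(or_w), bins=bins, alpha=0.6, color=_WOMEN_COLOR,
            label=f"women ({label}$_W$)")
    pcts = {"men": np.percentile(or_m, (2.5, 50, 97.5)),
            "women": np.percentile(or_w, (2.5, 50, 97.5))}
    for sex, color in (("men", _MEN_COLOR), ("women", _WOMEN_COLOR)):
        for v in pcts[sex]:
            ax.axvline(np.log(v), color=color, linestyle=":", linewidth=0.8)
    ticks = np.concatenate([pcts["men"], pcts["women"]])
    ax.set_xticks(np.log(ticks))
    ax.set_xticklabels([f"{v:.2f}" for v in ticks], rotation=45, fontsize=8)
    ax.set_xlabel("adjusted diet mortality odds ratio (log scale)")
    ax.set_ylabel("simulated studies")
    sens = (summary.sign_sens_shap if source == "shap" else summary.sign_sens_lr)
    title = (
        f"{summary.scenario_name}: power {100 * summary.power:.0f}%, "
        f"{label}$_W$ more protective in {100 * (sens or 0):.0f}% of "
        f"{summary.n_reps} studies"
    )
    ax.set_title(title, fontsize=10)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    _save(fig, path)


def shap_dependence_plot(
    shap: ShapMatrix,
    cohort: Cohort,
    path: str | Path,
    feature: str = "diet",
    color_by: str = "woman",
    jitter: float = 0.08,
    seed: int = 0,
) -> None:
    """Scatter of the diet-feature SHAP values against (jittered) diet
    status, colored by sex — the dependence-plot view in which a
    diet-by-sex interaction appears as a vertical separation of the two
    colors that differs between the two clouds."""
    phi = shap.feature(feature)
    x = cohort.column(feature).astype(float)
    group = cohort.column(color_by)
    rng = np.random.default_rng(seed)
    xj = x + rng.normal(0.0, jitter, size=x.size)
    fig, ax = plt.subplots(figsize=(6, 4))
    for value, color, label in ((0, _MEN_COLOR, "men"), (1, _WOMEN_COLOR, "women")):
        mask = group == value
        ax.scatter(xj[mask], phi[mask], s=3, alpha=0.25, color=color,
                   label=label, linewidths=0)
    ax.set_xticks([0, 1])
    ax.set_xticklabels([f"not healthy {feature}", f"healthy {feature}"])
    ax.set_ylabel(f"SHAP value of {feature} (log-odds)")
    ax.legend(frameon=False, fontsize=8, markerscale=4)
    fig.tight_layout()
    _save(fig, path)
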
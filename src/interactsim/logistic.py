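"""Multivariable logistic regression with a diet-by-sex product term.

The model carries all main effects plus one product term ``diet:woman``;
stratum-specific adjusted odds ratios follow from the fitted
coefficients (``exp(b_diet)`` among men, ``exp(b_diet + b_int)`` among
women) and the interaction is tested with a two-sided Wald statistic
against a standard normal reference.  Estimation is exact maximum
likelihood (Newton iterations, no regularization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import Cohort

__all__ = [
    "INTERACTION_TERM",
    "LogisticFit",
    "ORPair",
    "WaldResult",
    "fit_binary_design",
    "fit_logistic",
    "wald_interaction_test",
    "logistic_ors",
    "coefficient_table",
]

#: Name given to the diet-by-woman product column in the design matrix.
INTERACTION_TERM = "diet:woman"


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model: coefficients, covariance and diagnostics.

    ``params``/``cov`` are indexed by term name (``const``, the predictor
    columns, then ``diet:woman``); ``cov`` is the inverse observed
    information at the maximum.
    """

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_iter: int
    log_likelihood: float
    n_obs: int
    diagnostic: str = ""

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


@dataclass(frozen=True)
class ORPair:
    """Stratum-specific adjusted diet odds ratios (men, women)."""

    or_m_hat: float
    or_w_hat: float
    source: str  # "logistic" or "shap"

    def __post_init__(self) -> None:
        if not (self.or_m_hat > 0 and self.or_w_hat > 0):
            raise ValueError("odds ratios must be strictly positive")
        if self.source not in ("logistic", "shap"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class WaldResult:
    """Two-sided Wald test of the interaction coefficient."""

    z: float
    p: float


def fit_binary_design(
    y: np.ndarray, x: np.ndarray, names: list[str], add_constant: bool = True
) -> LogisticFit:
    """Maximum-likelihood logistic fit on an arbitrary binary design.

    Convergence: Newton steps until the parameter change is below 1e-8
    (statsmodels' criterion).  Perfect separation or a singular design is
    reported through ``converged = False`` with a diagnostic message
    rather than an exception, so replication harnesses can log and skip.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")
    if add_constant:
        design = np.column_stack([np.ones(len(y)), x])
        names = ["const"] + list(names)
    else:
        design = x
        names = list(names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(
                method="newton", tol=1e-8, maxiter=100, disp=0
            )
        cov = np.asarray(res.cov_params())
        return LogisticFit(
            params=pd.Series(res.params, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            converged=bool(res.mle_retvals.get("converged", True)),
            n_iter=int(res.mle_retvals.get("iterations", 0)),
            log_likelihood=float(res.llf),
            n_obs=len(y),
            diagnostic="",
        )
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        np.linalg.LinAlgError,
        ConvergenceWarning,
    ) as exc:
        nan = np.full(len(names), np.nan)
        return LogisticFit(
            params=pd.Series(nan, index=names),
            cov=pd.DataFrame(
                np.full((len(names), len(names)), np.nan),
                index=names,
                columns=names,
            ),
            converged=False,
            n_iter=0,
            log_likelihood=np.nan,
            n_obs=len(y),
            diagnostic=f"{type(exc).__name__}: {exc}",
        )


def fit_logistic(cohort: Cohort) -> LogisticFit:
    """Fit the full mortality model: 11 main effects + ``diet:woman``."""
    product = (cohort.diet * cohort.woman).astype(float)
    design = np.column_stack([cohort.x.astype(float), product])
    return fit_binary_design(
        cohort.y, design, list(cohort.columns) + [INTERACTION_TERM]
    )


def wald_interaction_test(fit: LogisticFit) -> WaldResult:
    """z = b_int / SE(b_int); p two-sided against the standard normal."""
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.diagnostic}")
    b = float(fit.params[INTERACTION_TERM])
    se = fit.se(INTERACTION_TERM)
    if not se > 0:
        raise ValueError("interaction coefficient has zero standard error")
    z = b / se
    return WaldResult(z=z, p=float(2.0 * norm.sf(abs(z))))


def logistic_ors(fit: LogisticFit) -> ORPair:
    """Stratum diet odds ratios: exp(b_diet) and exp(b_diet + b_int)."""
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.diagnostic}")
    b_diet = float(fit.params["diet"])
    b_int = float(fit.params[INTERACTION_TERM])
    return ORPair(
        or_m_hat=float(np.exp(b_diet)),
        or_w_hat=float(np.exp(b_diet + b_int)),
        source="logistic",
    )


def coefficient_table(fit: LogisticFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term estimates, SEs, Wald z/p, odds ratios and CIs."""
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.diagnostic}")
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for term in fit.params.index:
        est = float(fit.params[term])
        se = fit.se(term)
        z = est / se if se > 0 else np.nan
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "z": z,
                "p": float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                "or": float(np.exp(est)),
                "ci_low": float(np.exp(est - zcrit * se)),
                "ci_high": float(np.exp(est + zcrit * se)),
            }
        )
    return pd.DataFrame(rows)
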
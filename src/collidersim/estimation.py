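"""Regression machinery for the case-only progression analysis.

Everything the bias/coverage study needs: ordinary least squares and
maximum-likelihood logistic fits with 95% Wald intervals, the case-only
progression regression, and across-replicate summaries (mean coefficient,
empirical SD, mean model SE, CI coverage).  Fits are delegated to
statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .population import Population

__all__ = [
    "EffectEstimate",
    "ScenarioSummary",
    "fit_linear",
    "fit_logistic",
    "case_only_effect",
    "full_cohort_effect",
    "summarize_scenario",
    "EstimationError",
    "RankDeficientError",
    "Z_95",
]

#: Normal 95% quantile used for every Wald interval (t vs normal is
#: negligible at thousands of cases).
Z_95 = 1.96


class EstimationError(RuntimeError):
    pass


class RankDeficientError(EstimationError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear "
                         f"columns: {self.columns}")


@dataclass(frozen=True)
class EffectEstimate:
    """One fitted coefficient with its 95% Wald interval."""

    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    n_used: int
    covariate_label: str

    @classmethod
    def from_fit(cls, coef: float, se: float, n: int, label: str) -> "EffectEstimate":
        return cls(coefficient=float(coef), se=float(se),
                   ci_low=float(coef - Z_95 * se), ci_high=float(coef + Z_95 * se),
                   n_used=int(n), covariate_label=label)

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


@dataclass(frozen=True)
class ScenarioSummary:
    """Across-replicate summary of one covariate in one scenario."""

    mean_coefficient: float
    empirical_sd: float
    mean_model_se: float
    coverage_pct: float
    n_replicates_used: int
    true_value: float

    @property
    def mc_se(self) -> float:
        """Monte-Carlo SE of ``mean_coefficient``."""
        return self.empirical_sd / np.sqrt(self.n_replicates_used)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the offending columns: those lying in the span of the others
        bad = []
        for j, name in enumerate(X.columns):
            others = np.delete(mat, j, axis=1)
            resid = mat[:, j] - others @ np.linalg.lstsq(others, mat[:, j], rcond=None)[0]
            scale = np.linalg.norm(mat[:, j]) or 1.0
            if np.linalg.norm(resid) < 1e-8 * scale:
                bad.append(name)
        raise RankDeficientError(bad or list(X.columns))


def _as_design(design) -> pd.DataFrame:
    X = pd.DataFrame(design).astype(float)
    if X.isna().any().any():
        raise EstimationError("design contains missing values")
    return X


def fit_linear(outcome: Sequence[float], design) -> dict[str, EffectEstimate]:
    """OLS of ``outcome`` on ``design`` (an intercept is added) with
    model-based SEs; returns one :class:`EffectEstimate` per covariate."""
    X = _as_design(design)
    y = np.asarray(outcome, dtype=float)
    if np.isnan(y).any():
        raise EstimationError("outcome contains missing values")
    Xc = sm.add_constant(X, has_constant="add")
    _check_rank(Xc)
    res = sm.OLS(y, Xc).fit()
    return {
        name: EffectEstimate.from_fit(res.params[name], res.bse[name], len(y), name)
        for name in X.columns
    }


def fit_logistic(outcome: Sequence[int], design,
                 maxiter: int = 100) -> dict[str, EffectEstimate]:
    """Maximum-likelihood logistic fit (log-odds scale) with Wald CIs."""
    X = _as_design(design)
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise EstimationError("logistic outcome must be binary 0/1")
    Xc = sm.add_constant(X, has_constant="add")
    _check_rank(Xc)
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError("logistic fit did not converge")
    return {
        name: EffectEstimate.from_fit(res.params[name], res.bse[name], len(y), name)
        for name in X.columns
    }


def _design_from_labels(pop: Population, labels: Iterable[str],
                        mask: np.ndarray | None = None) -> pd.DataFrame:
    cols = {}
    for lab in labels:
        col = pop.column(lab)
        cols[lab] = col if mask is None else col[mask]
    return pd.DataFrame(cols)


def case_only_effect(pop: Population, target: str,
                     adjust_for: Sequence[str] = ()) -> EffectEstimate:
    """Progression regressed on ``target`` among cases only.

    The default is the univariable fit; pass ``adjust_for`` for covariate
    adjustment (e.g. ``["C"]``).
    """
    if pop.is_degenerate:
        raise EstimationError(f"degenerate replicate: {pop.degenerate_reason}")
    mask = pop.case_mask
    X = _design_from_labels(pop, [target, *adjust_for], mask)
    ests = fit_linear(pop.progression[mask], X)
    return ests[target]


def full_cohort_effect(pop: Population, target: str,
                       adjust_for: Sequence[str] = ()) -> EffectEstimate:
    """Unselected-population progression fit: a simulation-only oracle
    (progression is observable only among cases in a real design)."""
    X = _design_from_labels(pop, [target, *adjust_for])
    ests = fit_linear(pop.progression, X)
    return ests[target]


def summarize_scenario(estimates: Sequence[EffectEstimate],
                       true_value: float) -> ScenarioSummary:
    """Across-replicate mean, spread, and 95% CI coverage of the truth."""
    estimates = list(estimates)
    if len(estimates) < 2:
        raise EstimationError("need at least 2 non-degenerate estimates")
    coefs = np.array([e.coefficient for e in estimates])
    ses = np.array([e.se for e in estimates])
    covered = np.array([e.contains(true_value) for e in estimates])
    return ScenarioSummary(
        mean_coefficient=float(coefs.mean()),
        empirical_sd=float(coefs.std(ddof=1)),
        mean_model_se=float(ses.mean()),
        coverage_pct=float(100.0 * covered.mean()),
        n_replicates_used=len(estimates),
        true_value=float(true_value),
    )
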
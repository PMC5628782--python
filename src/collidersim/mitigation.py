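"""The four-step mitigation checklist for collider bias in case-only studies.

1. variant-incidence check: is the progression-associated variant also
   associated with disease incidence?
2. variant-confounder check: does the variant associate with confounders
   among cases but not in the overall population?
3. confounder adjustment: adjusting the case-only fit for measured
   confounders blocks the induced paths running through them (unmeasured
   confounding remains).
4. inverse-probability-of-selection weighting: weighting cases by
   1 / P(disease | covariates) undoes the selection; with the true
   probabilities (which include U) the estimate is consistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimation import (EffectEstimate, EstimationError, _design_from_labels,
                         case_only_effect, fit_linear, fit_logistic)
from .population import Population

__all__ = [
    "variant_incidence_check",
    "variant_confounder_check",
    "adjusted_case_only_effect",
    "ipw_case_only_effect",
    "checklist_report",
    "PairedEstimate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedEstimate:
    """The same association estimated among cases and in the full
    population; their discrepancy is the collider-bias diagnostic."""

    cases: EffectEstimate
    full: EffectEstimate

    @property
    def discrepancy(self) -> float:
        return self.cases.coefficient - self.full.coefficient


def variant_incidence_check(pop: Population, variant: str = "A") -> EffectEstimate:
    """Checklist 1: logistic fit of disease on the variant (log-OR scale)."""
    X = _design_from_labels(pop, [variant])
    return fit_logistic(pop.disease.astype(int), X)[variant]


def variant_confounder_check(pop: Population, variant: str = "A",
                             confounder: str = "C") -> PairedEstimate:
    """Checklist 2: linear fit of the confounder on the variant, among
    cases and in the full population."""
    mask = pop.case_mask
    full = fit_linear(pop.column(confounder),
                      _design_from_labels(pop, [variant]))[variant]
    cases = fit_linear(pop.column(confounder)[mask],
                       _design_from_labels(pop, [variant], mask))[variant]
    return PairedEstimate(cases=cases, full=full)


def adjusted_case_only_effect(pop: Population, target: str = "A",
                              confounders: Sequence[str] = ("C",)) -> EffectEstimate:
    """Checklist 3: case-only fit adjusted for the measured confounders."""
    return case_only_effect(pop, target, adjust_for=tuple(confounders))


def ipw_case_only_effect(pop: Population, target: str = "A",
                         weight_source: Union[str, Sequence[str]] = "true_probabilities",
                         adjust_for: Sequence[str] = (),
                         max_weight_ratio: float = 100.0,
                         truncate: bool = False,
                         robust_se: bool = False) -> EffectEstimate:
    """Checklist 4: weighted least squares among cases with selection
    weights 1 / P(disease | covariates).

    ``weight_source`` is either ``"true_probabilities"`` (the generative
    incidence probabilities, an oracle available only in simulation) or a
    sequence of covariate labels on which a logistic selection model is
    fitted in the full population.  Weights are rescaled to mean 1 among
    cases, which stabilises SEs without moving the point estimate.  A
    max/min weight ratio beyond ``max_weight_ratio`` triggers a warning,
    and truncation of the heaviest weights if ``truncate`` is set.
    """
    if pop.is_degenerate:
        raise EstimationError(f"degenerate replicate: {pop.degenerate_reason}")
    mask = pop.case_mask
    if isinstance(weight_source, str) and weight_source == "true_probabilities":
        p_case = pop.incidence_probability[mask]
    else:
        labels = list(weight_source)
        X_all = _design_from_labels(pop, labels)
        Xc = sm.add_constant(X_all.astype(float), has_constant="add")
        res = sm.Logit(pop.disease.astype(float), Xc).fit(disp=0)
        p_case = np.asarray(res.predict(Xc))[mask]
    w = 1.0 / p_case
    ratio = w.max() / w.min()
    if ratio > max_weight_ratio:
        msg = (f"selection-weight max/min ratio {ratio:.1f} exceeds "
               f"{max_weight_ratio:.1f}")
        if truncate:
            w = np.minimum(w, w.min() * max_weight_ratio)
            msg += "; heaviest weights truncated"
        warnings.warn(msg)
    w = w / w.mean()

    X = _design_from_labels(pop, [target, *adjust_for], mask)
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.WLS(pop.progression[mask], Xc, weights=w)
    res = model.fit(cov_type="HC1") if robust_se else model.fit()
    return EffectEstimate.from_fit(res.params[target], res.bse[target],
                                   int(mask.sum()), target)


def checklist_report(pop: Population, variants: Sequence[str] = ("A",),
                     confounders: Sequence[str] = ("C",)) -> pd.DataFrame:
    """Run checklist items 1-4 for each variant and tabulate the estimates.

    Emits estimates and CI-based flags (``warn`` when a 95% CI excludes 0
    for a diagnostic association), not verdicts: what variant-incidence
    effect size should trigger concern is a judgement call left to the
    analyst.
    """
    rows = []

    def flag(est: EffectEstimate) -> str:
        return "warn" if not est.contains(0.0) else "pass"

    for v in variants:
        inc = variant_incidence_check(pop, v)
        rows.append({"variant": v, "item": 1, "check": "variant-incidence",
                     "detail": "log-OR, full population",
                     "coefficient": inc.coefficient, "se": inc.se,
                     "ci_low": inc.ci_low, "ci_high": inc.ci_high,
                     "flag": flag(inc)})
        for conf in confounders:
            pair = variant_confounder_check(pop, v, conf)
            rows.append({"variant": v, "item": 2,
                         "check": f"variant-{conf} (cases)",
                         "detail": "induced association among cases",
                         "coefficient": pair.cases.coefficient,
                         "se": pair.cases.se, "ci_low": pair.cases.ci_low,
                         "ci_high": pair.cases.ci_high,
                         "flag": flag(pair.cases)})
            rows.append({"variant": v, "item": 2,
                         "check": f"variant-{conf} (full)",
                         "detail": "should be null in the overall population",
                         "coefficient": pair.full.coefficient,
                         "se": pair.full.se, "ci_low": pair.full.ci_low,
                         "ci_high": pair.full.ci_high,
                         "flag": flag(pair.full)})
        unadj = case_only_effect(pop, v)
        rows.append({"variant": v, "item": 3, "check": "case-only unadjusted",
                     "detail": "progression on variant, cases",
                     "coefficient": unadj.coefficient, "se": unadj.se,
                     "ci_low": unadj.ci_low, "ci_high": unadj.ci_high,
                     "flag": flag(unadj)})
        adj = adjusted_case_only_effect(pop, v, confounders)
        rows.append({"variant": v, "item": 3,
                     "check": f"case-only adjusted for {','.join(confounders)}",
                     "detail": "blocks measured-confounder paths only",
                     "coefficient": adj.coefficient, "se": adj.se,
                     "ci_low": adj.ci_low, "ci_high": adj.ci_high,
                     "flag": flag(adj)})
        ipw = ipw_case_only_effect(pop, v, "true_probabilities")
        rows.append({"variant": v, "item": 4, "check": "IPW (true weights)",
                     "detail": "oracle selection model incl. U",
                     "coefficient": ipw.coefficient, "se": ipw.se,
                     "ci_low": ipw.ci_low, "ci_high": ipw.ci_high,
                     "flag": flag(ipw)})
        fitted = ipw_case_only_effect(pop, v, [v, *confounders])
        rows.append({"variant": v, "item": 4,
                     "check": f"IPW (fitted on {','.join([v, *confounders])})",
                     "detail": "selection model omits U",
                     "coefficient": fitted.coefficient, "se": fitted.se,
                     "ci_low": fitted.ci_low, "ci_high": fitted.ci_high,
                     "flag": flag(fitted)})
    return pd.DataFrame(rows)


def render_checklist(report: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`checklist_report`."""
    lines = []
    for _, r in report.iterrows():
        lines.append(
            f"[item {r['item']}] {r['check']:38s} "
            f"coef={r['coefficient']:+.4f} (SE {r['se']:.4f}) "
            f"95% CI [{r['ci_low']:+.4f}, {r['ci_high']:+.4f}]  {r['flag'].upper()}"
            f"  -- {r['detail']}"
        )
    return "\n".join(lines)
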
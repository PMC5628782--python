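"""Case selection and instrument validity in Mendelian randomization.

An MR analysis of disease progression is run among cases by construction.
When the exposure (and hence its instrument, through the exposure) causes
disease, selecting cases induces an association between the instrument
and any other cause of disease or of the exposure — violating the
assumption that the instrument is independent of exposure-outcome
confounders.  The single-instrument Wald ratio computed in the case
stratum is then biased even when the true exposure effect on progression
is zero, while the full-cohort ratio (a simulation-only oracle) remains
consistent.
"""

from __future__ import annotations

import numpy as np

from .estimation import EffectEstimate, EstimationError, fit_linear, _design_from_labels
from .mitigation import PairedEstimate, variant_confounder_check
from .population import Population

__all__ = ["wald_ratio", "assumption2_diagnostic", "WeakInstrumentError"]


class WeakInstrumentError(EstimationError):
    def __init__(self, t_stat, threshold):
        self.t_stat = float(t_stat)
        super().__init__(
            f"weak instrument: first-stage |coef|/SE = {t_stat:.2f} "
            f"below threshold {threshold:.1f}"
        )


def wald_ratio(pop: Population, among: str = "cases",
               weak_t_threshold: float = 3.0) -> EffectEstimate:
    """Single-instrument Wald ratio beta_ZY / beta_ZX with delta-method SE.

    ``among`` selects the stratum: ``"cases"`` (the realistic progression
    design) or ``"all"`` (simulation-only oracle).  The first stage must
    satisfy |beta_ZX| / SE > ``weak_t_threshold``.
    """
    if pop.exposure is None:
        raise EstimationError("population has no exposure; simulate an MR scenario")
    if among == "cases":
        if pop.is_degenerate:
            raise EstimationError(f"degenerate replicate: {pop.degenerate_reason}")
        mask = pop.case_mask
    elif among == "all":
        mask = np.ones(len(pop), dtype=bool)
    else:
        raise ValueError("among must be 'cases' or 'all'")

    Z = _design_from_labels(pop, ["Z"], mask)
    first = fit_linear(pop.exposure[mask], Z)["Z"]
    t_stat = abs(first.coefficient) / first.se if first.se > 0 else np.inf
    if t_stat <= weak_t_threshold:
        raise WeakInstrumentError(t_stat, weak_t_threshold)
    reduced = fit_linear(pop.progression[mask], Z)["Z"]

    b_zx, se_zx = first.coefficient, first.se
    b_zy, se_zy = reduced.coefficient, reduced.se
    ratio = b_zy / b_zx
    # delta method, ignoring the (small) first/reduced covariance
    se = np.sqrt(se_zy**2 / b_zx**2 + (b_zy**2 * se_zx**2) / b_zx**4)
    return EffectEstimate.from_fit(ratio, se, int(mask.sum()),
                                   f"wald_ratio[{among}]")


def assumption2_diagnostic(pop: Population,
                           confounder: str = "U") -> PairedEstimate:
    """Instrument-confounder association among cases vs full population.

    A nonzero case-stratum association where the full-population one is
    null is the signature of selection-induced instrument invalidity.
    """
    if pop.exposure is None:
        raise EstimationError("population has no exposure; simulate an MR scenario")
    return variant_confounder_check(pop, "Z", confounder)
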
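"""Deterministic quadrature oracle for the expected case-only slope.

Independent cross-check of the Monte-Carlo simulation: the joint law of
(genotype, C, U) is enumerated/quadratured exactly, each cell is weighted
by its probability of being a case, and the expected univariable (or
covariate-adjusted) regression slope of progression on a target is the
weighted least-squares projection of E[progression | cell] on that target
under the case-weighted measure.  Residual progression noise is
independent of the covariates, so it does not enter the projection.

The intercept used here is itself calibrated by quadrature, keeping the
oracle fully independent of the simulation path.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit

from .scenarios import ScenarioSpec

__all__ = ["expected_case_only_slope_oracle", "oracle_intercept", "OracleGridError"]


class OracleGridError(RuntimeError):
    pass


def _grid(spec: ScenarioSpec, grid_size: int):
    if spec.n_u != 1:
        raise ValueError("the quadrature oracle supports a single U only")
    nodes, weights = hermegauss(grid_size)  # probabilists' Hermite: N(0,1)
    weights = weights / np.sqrt(2.0 * np.pi)
    g = np.array([0.0, 1.0, 2.0])
    pg = np.array([(1 - spec.maf_a) ** 2,
                   2 * spec.maf_a * (1 - spec.maf_a),
                   spec.maf_a ** 2])
    G, C, U = np.meshgrid(g, nodes, nodes, indexing="ij")
    W = pg[:, None, None] * weights[None, :, None] * weights[None, None, :]
    eta = (np.log(spec.or_a_incidence) * G
           + np.log(spec.or_c_incidence) * C
           + np.log(spec.or_u_incidence[0]) * U)
    return G, C, U, W, eta


def oracle_intercept(spec: ScenarioSpec, grid_size: int = 64) -> float:
    """Logistic intercept solving the quadrature prevalence equation."""
    _, _, _, W, eta = _grid(spec, grid_size)

    def gap(a):
        return float((W * expit(a + eta)).sum() - spec.target_prevalence)

    return brentq(gap, -20.0, 20.0, xtol=1e-12)


def _slope(spec: ScenarioSpec, target: str, grid_size: int,
           adjust_for: tuple[str, ...], selected: bool) -> float:
    G, C, U, W, eta = _grid(spec, grid_size)
    if selected:
        alpha = oracle_intercept(spec, grid_size)
        w = W * expit(alpha + eta)
    else:
        w = W.copy()
    w = w / w.sum()
    mean_prog = (spec.beta_a_progression * G
                 + spec.beta_c_progression * C
                 + spec.beta_u_progression[0] * U)
    cols = {"A": G, "C": C, "U": U}
    names = [target, *adjust_for]
    X = np.column_stack([np.ones(w.size)]
                        + [cols[n].ravel() for n in names])
    wf = w.ravel()
    y = mean_prog.ravel()
    XtW = X.T * wf
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    return float(beta[1])


def expected_case_only_slope_oracle(spec: ScenarioSpec, target: str = "A",
                                    grid_size: int = 64,
                                    adjust_for: tuple[str, ...] = (),
                                    selected: bool = True,
                                    refine_tol: float = 1e-3) -> float:
    """Expected case-only regression slope of progression on ``target``.

    ``selected=False`` drops the case weighting (prevalence weight ≡ 1),
    giving the unconditional projection — e.g. the slope for C is then
    exactly its causal progression effect.  The result is recomputed on a
    doubled grid; disagreement beyond ``refine_tol`` raises
    :class:`OracleGridError`.
    """
    coarse = _slope(spec, target, grid_size, tuple(adjust_for), selected)
    fine = _slope(spec, target, 2 * grid_size, tuple(adjust_for), selected)
    if abs(fine - coarse) > refine_tol:
        raise OracleGridError(
            f"slope changed by {abs(fine - coarse):.2e} on grid refinement "
            f"({grid_size} -> {2 * grid_size}); increase grid_size"
        )
    return fine
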
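"""Cohort generation under the incidence/progression causal diagram.

Disease incidence follows a logistic model whose intercept is calibrated
numerically so that the marginal prevalence hits the target (odds ratios
are the stated effect scale, and the convolution of binomial genotype and
normal confounder effects has no closed form).  Progression is a linear
Gaussian trait.  Replicate streams are spawned from the master seed with a
counter-based scheme, so each replicate is independently reproducible.
"""

from __future__ import annotations

import functools
import logging

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .population import Population
from .scenarios import MRScenarioSpec, ScenarioSpec

__all__ = [
    "calibrate_intercept",
    "simulate_population",
    "simulate_mr_population",
    "replicate_rng",
    "CalibrationError",
]

logger = logging.getLogger(__name__)

#: Fixed entropy for the calibration draw: the intercept depends only on the
#: science parameters, never on the master simulation seed.
CALIBRATION_SEED = 2023_05

#: Replicates with fewer cases than this are flagged degenerate.
MIN_CASES = 30


class CalibrationError(RuntimeError):
    pass


def replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate_index,))
    return np.random.default_rng(ss)


def _incidence_eta(spec: ScenarioSpec, genotype_a, c, u) -> np.ndarray:
    eta = (np.log(spec.or_a_incidence) * genotype_a
           + np.log(spec.or_c_incidence) * c)
    log_or_u = np.log(spec.or_u_incidence)
    eta = eta + (u if u.ndim == 2 else u[:, None]) @ log_or_u
    return eta


@functools.lru_cache(maxsize=128)
def _calibrate_cached(key, calibration_size, tolerance, calibration_seed):
    spec = ScenarioSpec(
        label="calibration",
        maf_a=key[0], or_a_incidence=key[1], or_c_incidence=key[2],
        or_u_incidence=key[3], beta_u_progression=tuple(0.0 for _ in key[3]),
        target_prevalence=key[4],
    )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=calibration_seed))
    g = rng.binomial(2, spec.maf_a, calibration_size).astype(float)
    c = rng.standard_normal(calibration_size)
    u = rng.standard_normal((calibration_size, spec.n_u))
    eta = _incidence_eta(spec, g, c, u)

    lo, hi = -20.0, 20.0

    def gap(a):
        return expit(a + eta).mean() - spec.target_prevalence

    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"prevalence target {spec.target_prevalence} not bracketed by "
            f"intercepts in [{lo}, {hi}]"
        )
    alpha = brentq(gap, lo, hi, xtol=1e-10, maxiter=200)
    achieved = expit(alpha + eta).mean()
    if abs(achieved - spec.target_prevalence) > tolerance:
        raise CalibrationError(
            f"calibrated prevalence {achieved:.4f} misses target "
            f"{spec.target_prevalence} by more than {tolerance}"
        )
    return float(alpha)


def calibrate_intercept(spec: ScenarioSpec, calibration_size: int = 1_000_000,
                        tolerance: float = 0.005,
                        calibration_seed: int = CALIBRATION_SEED) -> float:
    """Logistic intercept giving marginal prevalence ≈ ``target_prevalence``.

    Root-searches the Monte-Carlo prevalence of a large calibration draw;
    deterministic for a fixed ``calibration_seed`` and independent of the
    spec's master seed, so all replicates of one scenario share one
    intercept.
    """
    if calibration_size < 10**5:
        raise ValueError("calibration_size must be >= 1e5")
    key = (spec.maf_a, spec.or_a_incidence, spec.or_c_incidence,
           spec.or_u_incidence, spec.target_prevalence)
    return _calibrate_cached(key, calibration_size, tolerance, calibration_seed)


def _flag_degenerate(pop: Population, genotype) -> None:
    if pop.n_cases < MIN_CASES:
        pop.degenerate_reason = f"only {pop.n_cases} cases (< {MIN_CASES})"
    elif np.var(genotype[pop.case_mask]) == 0:
        pop.degenerate_reason = "zero genotype variance among cases"
    if pop.is_degenerate:
        logger.warning("replicate %d degenerate: %s",
                       pop.replicate_index, pop.degenerate_reason)


def simulate_population(spec: ScenarioSpec, replicate_index: int = 0,
                        intercept: float | None = None) -> Population:
    """Draw one cohort under the incidence/progression diagram.

    genotype_a ~ Binomial(2, maf); C, U independent standard normal;
    disease ~ Bernoulli(expit(alpha + log-OR terms)); progression is the
    linear combination of its causes plus Normal(0, residual_sd²) noise.
    """
    if intercept is None:
        intercept = calibrate_intercept(spec)
    rng = replicate_rng(spec.seed, replicate_index)
    n = spec.n_individuals
    g_a = rng.binomial(2, spec.maf_a, n).astype(float)
    g_b = rng.binomial(2, spec.maf_b, n).astype(float) if spec.include_b else None
    c = rng.standard_normal(n)
    u = rng.standard_normal((n, spec.n_u))
    p = expit(intercept + _incidence_eta(spec, g_a, c, u))
    disease = rng.random(n) < p
    progression = (spec.beta_a_progression * g_a
                   + spec.beta_c_progression * c
                   + u @ np.asarray(spec.beta_u_progression)
                   + rng.normal(0.0, spec.residual_sd, n))
    if g_b is not None:
        progression = progression + spec.beta_b_progression * g_b
    pop = Population(
        genotype_a=g_a, genotype_b=g_b, c=c,
        u=u[:, 0] if spec.n_u == 1 else u,
        disease=disease, progression=progression,
        incidence_probability=p, replicate_index=replicate_index,
    )
    _flag_degenerate(pop, g_a)
    return pop


def simulate_mr_population(mr_spec: MRScenarioSpec,
                           replicate_index: int = 0,
                           intercept: float | None = None) -> Population:
    """Draw one cohort under the Mendelian-randomization diagram.

    The instrument genotype is stored in ``genotype_a`` (alias ``Z``); the
    confounder of exposure and progression is stored in ``u``; exposure is
    continuous.  Disease depends on exposure (and optionally directly on
    the confounder); selecting cases therefore induces an
    instrument-confounder association whenever both affect incidence
    through any path.
    """
    rng = replicate_rng(mr_spec.seed, replicate_index)
    n = mr_spec.n_individuals
    z = rng.binomial(2, mr_spec.maf_instrument, n).astype(float)
    v = rng.standard_normal(n)
    x = (mr_spec.beta_instrument_exposure * z
         + mr_spec.beta_confounder_exposure * v
         + rng.normal(0.0, mr_spec.exposure_residual_sd, n))
    eta = (np.log(mr_spec.or_exposure_incidence) * x
           + np.log(mr_spec.or_confounder_incidence) * v)
    if intercept is None:
        intercept = _calibrate_mr_intercept(mr_spec)
    p = expit(intercept + eta)
    disease = rng.random(n) < p
    progression = (mr_spec.beta_exposure_progression * x
                   + mr_spec.beta_confounder_progression * v
                   + rng.normal(0.0, mr_spec.residual_sd, n))
    pop = Population(
        genotype_a=z, c=np.zeros(n), u=v, disease=disease,
        progression=progression, incidence_probability=p,
        exposure=x, replicate_index=replicate_index,
    )
    _flag_degenerate(pop, z)
    return pop


@functools.lru_cache(maxsize=64)
def _calibrate_mr_cached(key, calibration_size, tolerance, calibration_seed):
    (maf, b_zx, or_x, b_vx, or_v, sd_x, target) = key
    rng = np.random.default_rng(np.random.SeedSequence(entropy=calibration_seed))
    z = rng.binomial(2, maf, calibration_size).astype(float)
    v = rng.standard_normal(calibration_size)
    x = b_zx * z + b_vx * v + rng.normal(0.0, sd_x, calibration_size)
    eta = np.log(or_x) * x + np.log(or_v) * v

    def gap(a):
        return expit(a + eta).mean() - target

    if gap(-20.0) > 0 or gap(20.0) < 0:
        raise CalibrationError(
            f"prevalence target {target} not bracketed by intercepts in [-20, 20]")
    alpha = brentq(gap, -20.0, 20.0, xtol=1e-10, maxiter=200)
    if abs(expit(alpha + eta).mean() - target) > tolerance:
        raise CalibrationError("MR intercept calibration missed its tolerance")
    return float(alpha)


def _calibrate_mr_intercept(mr_spec: MRScenarioSpec,
                            calibration_size: int = 1_000_000,
                            tolerance: float = 0.005,
                            calibration_seed: int = CALIBRATION_SEED) -> float:
    key = (mr_spec.maf_instrument, mr_spec.beta_instrument_exposure,
           mr_spec.or_exposure_incidence, mr_spec.beta_confounder_exposure,
           mr_spec.or_confounder_incidence, mr_spec.exposure_residual_sd,
           mr_spec.target_prevalence)
    return _calibrate_mr_cached(key, calibration_size, tolerance, calibration_seed)
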
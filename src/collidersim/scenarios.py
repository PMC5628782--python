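"""Scenario specifications for the collider-bias simulation study.

A :class:`ScenarioSpec` holds every generative parameter of one confounding
regime in the case-only progression design: a biallelic variant A that
affects disease incidence only, an optional variant B that affects
progression only, a measured confounder C and one or more unmeasured
confounders U that affect both incidence and progression.  Disease is
binary with a calibrated marginal prevalence; progression is a continuous
trait observed among cases.

The four named presets (``low``/``moderate``/``high``/``strong``) index the
strength of unmeasured confounding via the pair (incidence odds ratio of U,
progression effect of U): (1.5, 0.5), (2, 0.8), (2.5, 1), (3, 1.5).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Mapping, Union

import yaml

__all__ = [
    "ScenarioSpec",
    "MRScenarioSpec",
    "PRESETS",
    "PRESET_LABELS",
    "preset",
    "load_scenario",
    "save_scenario",
    "DEFAULT_RESIDUAL_SD",
]

#: Progression residual SD. Calibrated so that the model-based standard
#: errors of the case-only fits at ~10,000 cases reproduce the reference
#: per-cell SEs (0.01-0.03 for A, 0.01-0.02 for C); see docs/methods.md.
DEFAULT_RESIDUAL_SD = 0.65

_FloatOrTuple = Union[float, tuple]


def _as_tuple(x) -> tuple:
    if isinstance(x, (list, tuple)):
        return tuple(float(v) for v in x)
    return (float(x),)


@dataclass(frozen=True)
class ScenarioSpec:
    """All generative parameters for one confounding regime.

    ``or_u_incidence`` / ``beta_u_progression`` may be scalars (single
    unmeasured confounder, the default design) or equal-length sequences
    (several independent standard-normal U's).
    """

    label: str = "custom"
    n_individuals: int = 50_000
    n_replicates: int = 500
    maf_a: float = 0.2
    or_a_incidence: float = 1.3
    beta_a_progression: float = 0.0
    maf_b: float = 0.2
    include_b: bool = False
    beta_b_progression: float = 0.1
    or_c_incidence: float = 1.3
    beta_c_progression: float = 0.1
    or_u_incidence: _FloatOrTuple = 1.5
    beta_u_progression: _FloatOrTuple = 0.5
    target_prevalence: float = 0.2
    residual_sd: float = DEFAULT_RESIDUAL_SD
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "or_u_incidence", _as_tuple(self.or_u_incidence))
        object.__setattr__(self, "beta_u_progression", _as_tuple(self.beta_u_progression))
        if len(self.or_u_incidence) != len(self.beta_u_progression):
            raise ValueError(
                "or_u_incidence and beta_u_progression must have the same length"
            )
        for name in ("or_a_incidence", "or_c_incidence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v <= 0 for v in self.or_u_incidence):
            raise ValueError("or_u_incidence entries must be > 0")
        for name in ("maf_a", "maf_b"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_individuals < 100:
            raise ValueError("n_individuals must be >= 100")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")

    @property
    def n_u(self) -> int:
        """Number of unmeasured confounders."""
        return len(self.or_u_incidence)

    def with_(self, **kwargs) -> "ScenarioSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.n_u == 1:
            d["or_u_incidence"] = self.or_u_incidence[0]
            d["beta_u_progression"] = self.beta_u_progression[0]
        else:
            d["or_u_incidence"] = list(self.or_u_incidence)
            d["beta_u_progression"] = list(self.beta_u_progression)
        return d


#: (incidence OR of U, progression effect of U) by confounding strength.
PRESETS: dict[str, tuple[float, float]] = {
    "low": (1.5, 0.5),
    "moderate": (2.0, 0.8),
    "high": (2.5, 1.0),
    "strong": (3.0, 1.5),
}

PRESET_LABELS = tuple(PRESETS)


def preset(label: str, **overrides) -> ScenarioSpec:
    """Build the named confounding scenario, optionally overriding fields."""
    try:
        or_u, beta_u = PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown scenario {label!r}; valid labels: {', '.join(PRESET_LABELS)}"
        ) from None
    return ScenarioSpec(
        label=label, or_u_incidence=or_u, beta_u_progression=beta_u, **overrides
    )


@dataclass(frozen=True)
class MRScenarioSpec:
    """Generative parameters for the Mendelian-randomization demonstration.

    A genetic instrument Z affects a continuous exposure X, X affects
    disease incidence (and, if ``beta_exposure_progression`` is nonzero,
    progression), and a confounder V affects both exposure and progression
    (and optionally incidence directly).  Selecting cases then induces an
    instrument-confounder association, violating instrument validity.

    Default effect sizes are illustrative, not reproductions of any
    published table; they are sized so the selection-induced bias is
    clearly visible in a few dozen replicates (see docs/methods.md).
    """

    label: str = "mr"
    n_individuals: int = 50_000
    n_replicates: int = 200
    maf_instrument: float = 0.3
    beta_instrument_exposure: float = 0.5
    beta_exposure_progression: float = 0.0
    or_exposure_incidence: float = 2.5
    beta_confounder_exposure: float = 0.7
    beta_confounder_progression: float = 0.5
    or_confounder_incidence: float = 1.0
    exposure_residual_sd: float = 0.8
    target_prevalence: float = 0.2
    residual_sd: float = DEFAULT_RESIDUAL_SD
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.maf_instrument < 1:
            raise ValueError("maf_instrument must lie in (0, 1)")
        for name in ("or_exposure_incidence", "or_confounder_incidence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_individuals < 100:
            raise ValueError("n_individuals must be >= 100")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        for name in ("exposure_residual_sd", "residual_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_(self, **kwargs) -> "MRScenarioSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


_SCENARIO_FIELDS = {f.name for f in fields(ScenarioSpec)}
_MR_FIELDS = {f.name for f in fields(MRScenarioSpec)}


def load_scenario(source: Union[str, Path, Mapping], mr: bool = False):
    """Load a :class:`ScenarioSpec` (or :class:`MRScenarioSpec`) from a YAML
    file or a mapping whose keys are the spec's field names.

    A ``scenario:`` key naming a preset may be given instead of explicit
    ``or_u_incidence`` / ``beta_u_progression``; other keys override the
    preset's defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if mr:
        unknown = set(data) - _MR_FIELDS
        if unknown:
            raise ValueError(f"unknown MR scenario keys: {sorted(unknown)}")
        return MRScenarioSpec(**data)
    label = data.pop("scenario", None)
    unknown = set(data) - _SCENARIO_FIELDS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if label is not None:
        return preset(label, **data)
    return ScenarioSpec(**data)


def save_scenario(spec, path: Union[str, Path]) -> None:
    """Write a spec to YAML with keys equal to its field names."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
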
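"""Per-individual synthetic cohort container."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["Population", "COVARIATE_ALIASES"]

# Friendly labels for covariates, matching the letters used throughout the
# causal-diagram discussion: A (incidence-only variant), B (progression-only
# variant), C (measured confounder), U (unmeasured confounder), X (exposure),
# Z (instrument, which in MR populations is stored as genotype_a).
COVARIATE_ALIASES = {
    "A": "genotype_a",
    "B": "genotype_b",
    "C": "c",
    "U": "u",
    "X": "exposure",
    "Z": "genotype_a",
}


@dataclass
class Population:
    """One simulated cohort.

    Progression is generated for every individual but is regarded as
    observed only among cases; full-cohort progression fits are a
    simulation-only oracle.  ``incidence_probability`` retains the true
    P(disease | covariates) for oracle inverse-probability weighting.
    """

    genotype_a: np.ndarray
    c: np.ndarray
    u: np.ndarray  # shape (n,) for one U, (n, k) for several
    disease: np.ndarray
    progression: np.ndarray
    incidence_probability: np.ndarray
    genotype_b: Optional[np.ndarray] = None
    exposure: Optional[np.ndarray] = None
    replicate_index: int = 0
    degenerate_reason: Optional[str] = None

    def __post_init__(self):
        n = len(self.genotype_a)
        for name in ("c", "u", "disease", "progression", "incidence_probability",
                     "genotype_b", "exposure"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"length of {name} ({len(arr)}) != {n}")
        p = self.incidence_probability
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("incidence_probability must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return len(self.genotype_a)

    @property
    def case_mask(self) -> np.ndarray:
        return self.disease.astype(bool)

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def is_degenerate(self) -> bool:
        return self.degenerate_reason is not None

    def column(self, label: str) -> np.ndarray:
        """Covariate values by field name or one-letter alias (A/B/C/U/X/Z)."""
        name = COVARIATE_ALIASES.get(label, label)
        arr = getattr(self, name, None)
        if arr is None:
            raise KeyError(f"population has no covariate {label!r}")
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:  # several U's: the alias refers to the first
            arr = arr[:, 0]
        return arr

    def to_frame(self) -> pd.DataFrame:
        """Flat per-individual table with the canonical export columns."""
        n = len(self)
        df = pd.DataFrame({
            "id": np.arange(n),
            "genotype_a": self.genotype_a.astype(int),
            "genotype_b": (self.genotype_b.astype(int)
                           if self.genotype_b is not None else pd.array([pd.NA] * n)),
            "c": self.c,
            "u": self.u if np.ndim(self.u) == 1 else np.asarray(self.u)[:, 0],
            "disease": self.disease.astype(int),
            "progression": self.progression,
        })
        if self.exposure is not None:
            df["exposure"] = self.exposure
        return df

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)
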
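import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import collidersim as cs

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def low_pop():
    """One low-confounding cohort at the default population size."""
    return cs.simulate_population(cs.preset("low", seed=101), 0)


@pytest.fixture(scope="session")
def strong_pop():
    """One strong-confounding cohort at the default population size."""
    return cs.simulate_population(cs.preset("strong", seed=101), 0)


@pytest.fixture(scope="session")
def table1_200():
    """The four-scenario study at the desk-scale replicate count.

    Shared between the reproduction, oracle-agreement, and monotonicity
    checks so the simulation only runs once per session.
    """
    return cs.run_table1(seed=11, n_replicates=200)


def mean_and_mcse(values):
    v = np.asarray(values, dtype=float)
    return v.mean(), v.std(ddof=1) / np.sqrt(len(v))
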
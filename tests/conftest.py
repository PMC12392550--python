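import numpy as np
import pandas as pd
import pytest

from coda24 import CohortParams, OutcomeModel, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort under the documented defaults."""
    return simulate_cohort(seed=42)


@pytest.fixture(scope="session")
def default_records(default_cohort):
    return default_cohort.records


@pytest.fixture(scope="session")
def noiseless_records():
    """Outcome is an exact linear function of (ilr1, ilr2, age, sex)."""
    params = CohortParams(
        n_children=80,
        dropout_prob=0.0,
        outcomes={"gm_raw": OutcomeModel(27.0, 8.5, 6.0, 1.1, 0.5, tau=0.0, sigma=0.0)},
    )
    return simulate_cohort(params, seed=7).records


def random_compositions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Strictly positive random triples spanning several orders of magnitude."""
    return np.exp(rng.uniform(np.log(1e-3), np.log(1e3), size=(n, 3)))
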
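import numpy as np
import pandas as pd
import pytest

from subtypecurves import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, strongly separable cohort shared across tests."""
    return simulate_cohort(CohortConfig(
        n_samples=200, n_genes=400, n_informative=80,
        effect_size=1.5, dispersion=0.15, seed=2))


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort: no subtype signal, no marker shift."""
    return simulate_cohort(CohortConfig(
        n_samples=200, n_genes=100, n_informative=20,
        effect_size=0.0, marker_shift=0.0, seed=5))


@pytest.fixture()
def tiny_counts():
    rng = np.random.default_rng(17)
    values = rng.integers(1, 500, size=(50, 6))
    return pd.DataFrame(values,
                        index=[f"G{i:03d}" for i in range(50)],
                        columns=[f"S{j}" for j in range(6)])
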
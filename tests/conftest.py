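import warnings

import numpy as np
import pytest

from methexpress import SimulationConfig, simulate_dataset
from methexpress.pipeline import load_fixture_tables


@pytest.fixture(scope="session")
def fixture_tables():
    """The two 15-row candidate tables shipped with the package."""
    return load_fixture_tables()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic dataset with planted DM/DE/coupling structure."""
    cfg = SimulationConfig(
        n_pairs=6, n_probes=1500, n_genes=400, frac_dml=0.08,
        delta_beta_effect=0.3, frac_deg=0.08, lfc_effect=2.0, seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
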
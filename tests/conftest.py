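import numpy as np
import pandas as pd
import pytest

from microbreed import coda
from microbreed.gblup import McmcConfig
from microbreed.simulate import SimulationSpec, simulate_population


@pytest.fixture(scope="session")
def pop_small():
    """120-animal synthetic study shared across test modules."""
    return simulate_population(
        SimulationSpec(n_animals=120, n_snps=600, n_features=30, seed=42)
    )


@pytest.fixture(scope="session")
def alr_small(pop_small):
    """alr-transformed core features of the shared population."""
    core, _ = coda.filter_core(pop_small.microbiome)
    replaced = coda.replace_zeros_gbm(core)
    ref = coda.select_alr_reference(replaced)
    return coda.alr_transform(replaced, ref.best).to_frame()


@pytest.fixture(scope="session")
def quick_cfg():
    """Short chain for structural tests (not for inference accuracy)."""
    return McmcConfig(n_iter=2000, burn_in=400, thin=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_composition(values, sample_prefix="s", part_prefix="p"):
    values = np.asarray(values, float)
    n, j = values.shape
    return coda.CompositionTable(
        [f"{sample_prefix}{i}" for i in range(n)],
        [f"{part_prefix}{k}" for k in range(j)],
        values,
    )


@pytest.fixture(scope="session")
def make_table():
    return make_composition
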
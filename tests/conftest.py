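import numpy as np
import pandas as pd
import pytest

from lakecohorts import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast community: 2 cohorts of 8 on 24 background species."""
    return SimulationConfig(
        n_species=40,
        n_samples=60,
        cohort_sizes=(8, 8),
        genome_length_range=(3e5, 6e5),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    catalog, true_sizes = simulate.simulate_catalog(small_config)
    return catalog, true_sizes


@pytest.fixture(scope="session")
def small_community(small_config, small_catalog):
    catalog, _ = small_catalog
    abundance, labels, env = simulate.simulate_abundances(catalog, small_config)
    return abundance, labels, env


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_config):
    """A persisted simulated run directory (depth profiles + KO tables)."""
    outdir = tmp_path_factory.mktemp("run")
    truth = simulate.simulate_run(small_config, outdir)
    return outdir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def iid_lognormal_fractions(n_species: int, n_samples: int, seed: int) -> pd.DataFrame:
    """Closed i.i.d. log-normal abundances: the no-association null."""
    r = np.random.default_rng(seed)
    x = np.exp(r.normal(0.0, 1.0, size=(n_species, n_samples)))
    x /= x.sum(axis=0, keepdims=True)
    return pd.DataFrame(x)
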
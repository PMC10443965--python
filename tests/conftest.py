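import logging
import warnings

import pytest

from mirscreen import SimConfig, run_pipeline, simulate_dataset

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", category=FutureWarning)


def small_config(**overrides) -> SimConfig:
    """A scaled-down generator config for fast unit tests."""
    defaults = dict(
        n_genes=400,
        n_mirnas=60,
        genes_per_archetype=40,
        n_regulators=3,
        targets_per_regulator=25,
        decoy_targets_per_mirna=10,
        deafness_set_size=20,
        deafness_in_archetype=15,
        seed=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size default fixture (study-condition scale), seed 1."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return run_pipeline(ds.mrna, ds.mirna, ds.targets, ds.gene_sets)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_result(small_dataset):
    ds = small_dataset
    return run_pipeline(ds.mrna, ds.mirna, ds.targets, ds.gene_sets)
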
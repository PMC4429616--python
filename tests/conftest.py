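import pytest

from dcgscan import SimulationConfig, simulate_dataset
from dcgscan.io_preprocess import preprocess_dataset


@pytest.fixture(scope="session")
def cohort():
    """Small 450K-style cohort with planted DCGs, shared across tests."""
    config = SimulationConfig(
        n_genes=120, n_tumor=30, n_normal=12, dcg_fraction=0.25, seed=42
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def preprocessed(cohort):
    return preprocess_dataset(
        cohort.expression, cohort.methylation, cohort.annotation, cohort.groups
    )
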
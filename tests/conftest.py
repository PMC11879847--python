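import numpy as np
import pandas as pd
import pytest

from lpsprofiler import SimulationConfig, generate_pangenomes, generate_taxa_profiles


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_species=40, n_samples_per_arm=12, n_batches=2, seed=11)


@pytest.fixture
def small_cohort(small_config):
    """(pangenome, truth, taxa, metadata) for a small planted cohort."""
    pangenome, truth = generate_pangenomes(small_config)
    taxa, metadata = generate_taxa_profiles(small_config, truth)
    return pangenome, truth, taxa, metadata


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_count_matrix(
    rng: np.random.Generator, n_features: int = 20, n_samples: int = 8
) -> pd.DataFrame:
    counts = rng.poisson(30, size=(n_features, n_samples)) + 1
    return pd.DataFrame(
        counts,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
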
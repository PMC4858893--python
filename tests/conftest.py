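import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scmtseq.synthetic import SyntheticConfig, generate_dataset, generate_reference

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# small-but-complete study: every planted feature class present, seconds to run
SMALL_KWARGS = dict(
    n_genes=120, n_cells=8, chrom_length=320_000, n_snps=40,
    n_variable_promoters=8, n_variable_genebodies=8, n_hyper_high=3,
    n_allelic_genes=4, n_lambda_sites=400, seed=11,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(**SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_reference(small_dataset):
    return small_dataset.reference


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_calls():
    """Hand-written call table: 4 sites, known levels."""
    return pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "pos": [10, 20, 30, 40],
        "meth": [0, 3, 5, 9],
        "total": [4, 6, 5, 9],
        "level": [0.0, 0.5, 1.0, 1.0],
    })
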
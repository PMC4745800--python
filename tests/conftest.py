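import numpy as np
import pandas as pd
import pytest

from rppamet import ExpressionMatrix, RPPAMatrix, SimConfig, generate_two_datasets


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study conditions for fast end-to-end tests."""
    return SimConfig(
        n_samples_derivation=120,
        n_samples_validation=80,
        n_proteins=6,
        n_informative_proteins=3,
        genes_per_metagene=30,
        n_genes_total=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return generate_two_datasets(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_expr():
    """4 genes x 6 samples with hand-checkable values."""
    genes = ["A", "B", "C", "D"]
    samples = [f"S{i}" for i in range(1, 7)]
    values = np.arange(24, dtype=float).reshape(4, 6) + 1.0
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
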
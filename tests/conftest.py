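import numpy as np
import pandas as pd
import pytest

from t2dbrain import CohortConfig, generate_cohort
from t2dbrain.synthetic import generate_annotation


@pytest.fixture(scope="session")
def small_cohort():
    """400 genes, 3 modules of 60, planted effects; shared across tests."""
    cfg = CohortConfig(
        n_genes=400, n_cases=15, n_controls=40, n_modules=3, module_size=60,
        de_fraction=0.15, lfc=1.0, batch_effect=0.8, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects at all: de_fraction=0, no batch, no modules."""
    cfg = CohortConfig(
        n_genes=500, n_cases=20, n_controls=40, n_modules=0, module_size=0,
        de_fraction=0.0, lfc=0.0, batch_effect=0.0, covariate_imbalance=0.0,
        seed=12,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clustered_annotation():
    cfg = CohortConfig(n_genes=600, n_cases=10, n_controls=20, n_modules=2,
                       module_size=60, de_fraction=0.1, seed=13)
    counts, samples, truth = generate_cohort(cfg)
    ann = generate_annotation(600, n_chromosomes=8, cluster_de=True, truth=truth, seed=13)
    return ann, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
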
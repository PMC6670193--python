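import numpy as np
import pandas as pd
import pytest

import coabund as cb


@pytest.fixture(scope="session")
def planted():
    """Default planted cohort: 20 CAGs of 10-50 genes, mild gene noise."""
    config = cb.SimulationConfig(seed=1)
    matrix, meta, truth = cb.simulate_cohort(config)
    return matrix, meta, truth


@pytest.fixture(scope="session")
def small_catalog():
    """Many small CAGs (2-5 genes), the shape used for association tests."""
    config = cb.SimulationConfig(
        seed=2, n_cags=100, genes_per_cag=(2, 5), n_samples=60, n_subjects=60
    )
    matrix, meta, truth = cb.simulate_cohort(config)
    return matrix, meta, truth


@pytest.fixture
def toy_matrix():
    df = pd.DataFrame(
        [[2.0, 4.0], [3.0, 6.0], [5.0, 10.0]],
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
        columns=pd.Index(["s1", "s2"], name="sample"),
    )
    return cb.GeneAbundanceMatrix(df)
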
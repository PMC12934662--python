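import numpy as np
import pandas as pd
import pytest

from amgrn import syndata
from amgrn.core import normalize_log1p, pca_scores


SMALL = dict(
    n_cells_per_population=150,
    n_genes=200,
    n_tfs=10,
    library_size_mean=3000,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return syndata.SyntheticConfig(**SMALL)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return syndata.generate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_truth, small_config):
    return syndata.simulate_counts(small_truth, small_config)


@pytest.fixture(scope="session")
def small_embedding(small_counts):
    X = normalize_log1p(small_counts)
    return pd.DataFrame(pca_scores(X.to_numpy(), 2), index=X.index,
                        columns=["x", "y"])
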
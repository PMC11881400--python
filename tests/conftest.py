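import numpy as np
import pytest

from chemuq import (MLPConfig, MLPModel, SyntheticConfig, gen_fingerprint_dataset,
                    make_split)


@pytest.fixture(scope="session")
def small_synthetic():
    """Desk-scale clustered dataset with known logistic ground truth."""
    cfg = SyntheticConfig(n_compounds=800, n_features=256, n_clusters=20,
                          bits_per_compound=30, seed=1)
    data, true_w, true_p = gen_fingerprint_dataset(cfg)
    return data, true_w, true_p


@pytest.fixture(scope="session")
def split():
    return make_split(valid_fold=3, test_fold=4)


@pytest.fixture(scope="session")
def trained_mlp(small_synthetic, split):
    data, _, _ = small_synthetic
    cfg = MLPConfig(hidden_size=16, dropout_rate=0.2, max_epochs=20, seed=0)
    return MLPModel(data, split, cfg).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
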
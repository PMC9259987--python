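import numpy as np
import pytest

from dpomics import SyntheticConfig, gen_dataset, gen_expression


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lowrank_fixture():
    """Rank-5 expression matrix, n=512 x d=64, for descent and oracle tests."""
    cfg = SyntheticConfig(
        n_samples=512, n_features=64, latent_dim=5, noise_std=0.5, seed=7
    )
    return gen_expression(cfg)


@pytest.fixture(scope="session")
def labeled_fixture():
    """Small full dataset (expression + labels + drug responses)."""
    cfg = SyntheticConfig(
        n_samples=300, n_features=40, latent_dim=5, noise_std=0.5,
        class_effect=3.0, n_drugs=3, seed=11,
    )
    return gen_dataset(cfg)
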
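import numpy as np
import pandas as pd
import pytest

from magniche.synthetic_data import SyntheticConfig, build_world


@pytest.fixture(scope="session")
def small_world():
    """A small deterministic world shared by read-only tests."""
    cfg = SyntheticConfig(
        n_taxa=40, n_samples=30, n_genes=200, n_niche_genes=20, seed=7
    )
    return build_world(cfg)


@pytest.fixture(scope="session")
def beta1_world():
    """Gene-determined niche world used by prediction tests."""
    cfg = SyntheticConfig(
        n_taxa=120,
        n_samples=60,
        n_genes=300,
        n_niche_genes=30,
        beta=1.0,
        noise_sd=0.2,
        seed=21,
    )
    return build_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dissimilarity(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random symmetric dissimilarity matrix with zero diagonal."""
    raw = rng.uniform(0.05, 1.0, size=(n, n))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"e{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids)
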
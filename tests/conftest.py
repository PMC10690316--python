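import numpy as np
import pytest

from multifuse import standardize
from multifuse.simulate import (MultiViewScenario, PhylogenyScenario,
                                gen_multiview, gen_phylogeny)
from multifuse.viral import train_skipgram


def standardized_pair(n, p, q, seed):
    """Random standardized views for oracle comparisons."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Z = rng.standard_normal((n, q))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    return X, Z


@pytest.fixture(scope="session")
def default_multiview():
    """Default latent-factor scenario with its planted truth, standardized."""
    dataset, truth = gen_multiview(MultiViewScenario(seed=0))
    dataset_std, _ = standardize(dataset)
    return dataset_std, truth


@pytest.fixture(scope="session")
def default_phylogeny():
    return gen_phylogeny(PhylogenyScenario(seed=3))


@pytest.fixture(scope="session")
def default_embedding(default_phylogeny):
    catalog, _ = default_phylogeny
    return train_skipgram(catalog, d=16, window=200, epochs=10, seed=1)


def sign_aligned_cosine(a, b):
    return abs(float(a @ b)) / (np.linalg.norm(a) * np.linalg.norm(b))
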
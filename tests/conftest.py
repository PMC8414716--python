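"""Shared fixtures: toy networks and synthetic datasets, generated in-process."""

import numpy as np
import pytest
from hypothesis import settings

from hetdti import (
    BineHyperparams,
    BipartiteDTINetwork,
    EntityRegistry,
    SimilarityMatrix,
    SyntheticSpec,
    generate_dataset,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

# scaled-down training profile used for synthetic-data experiments
SMALL_BINE = BineHyperparams(dim=16, max_iter=10, max_walks=8, ws=3)


@pytest.fixture
def toy_network() -> BipartiteDTINetwork:
    """3 drugs x 2 targets: Drug1-{T2}, Drug2-{T1,T2}, Drug3-{T1}."""
    reg = EntityRegistry(("Drug1", "Drug2", "Drug3"), ("Target1", "Target2"))
    return BipartiteDTINetwork(reg, np.array([[0, 1], [1, 1], [1, 0]], dtype=float))


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default planted-block dataset (30 x 24, 12 blocks)."""
    return generate_dataset(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def screen_dataset():
    """Default dataset with injected duplicate and near-uniform views."""
    return generate_dataset(SyntheticSpec(seed=1, n_redundant=2, n_uniform=2))


def random_similarity(rng: np.random.Generator, side: str, name: str, k: int) -> SimilarityMatrix:
    """A random symmetric [0, 1] similarity matrix with unit diagonal."""
    a = rng.random((k, k))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(side, name, a)
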
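import numpy as np
import pytest

from atlasfuse.atlas import AtlasSpec
from atlasfuse.fc_graphs import BrainGraph, FCMatrix, knn_sparsify


def random_fc(rng: np.random.Generator, n: int, atlas: AtlasSpec | None = None) -> FCMatrix:
    """A random valid FC matrix with distinct off-diagonal entries."""
    x = rng.standard_normal((n * 3, n))
    values = np.corrcoef(x, rowvar=False)
    atlas = atlas or AtlasSpec.generic(f"rand{n}", n)
    return FCMatrix("sub-r", atlas, values)


def random_graph(rng: np.random.Generator, n: int, k: int = 3) -> BrainGraph:
    return knn_sparsify(random_fc(rng, n), k=k)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_atlas():
    return AtlasSpec.generic("small5", 5)


@pytest.fixture(scope="session")
def path_graph():
    """Unweighted path 0-1-2-3-4 as a BrainGraph."""
    adj = np.zeros((5, 5))
    for i in range(4):
        adj[i, i + 1] = adj[i + 1, i] = 0.5
    features = np.eye(5)
    return BrainGraph("sub-p", AtlasSpec.generic("path5", 5), adj, features, 0)
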
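import numpy as np
import pytest

from regmaxs import Morphology, TreeGenParams, generate_tree


@pytest.fixture
def toy3() -> Morphology:
    """Three-node L-shaped morphology from a minimal SWC."""
    return Morphology(ids=[1, 2, 3], types=[1, 3, 3],
                      xyz=[[0, 0, 0], [10, 0, 0], [10, 10, 0]],
                      radii=[1, 1, 1], parents=[-1, 1, 2])


@pytest.fixture
def line3() -> Morphology:
    """Three collinear connected nodes spaced 10 um apart."""
    return Morphology(ids=[1, 2, 3], types=[1, 3, 3],
                      xyz=[[0, 0, 0], [10, 0, 0], [20, 0, 0]],
                      radii=[1, 1, 1], parents=[-1, 1, 2])


@pytest.fixture(scope="session")
def small_tree() -> Morphology:
    """Fast 80-node synthetic arbor for registration unit tests."""
    return generate_tree(TreeGenParams(n_nodes=80,
                                       spatial_extent=(120.0, 120.0, 30.0),
                                       seed=1))


@pytest.fixture(scope="session")
def default_tree() -> Morphology:
    """The 300-node default synthetic arbor."""
    return generate_tree(TreeGenParams(seed=3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
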
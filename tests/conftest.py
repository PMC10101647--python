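import numpy as np
import pytest

from arbordyn.simulate import make_binary_tree, make_y_tree, random_arbor


@pytest.fixture
def y_arbor():
    """Y-shape: 10 μm stem, two 5 μm terminal branches."""
    return make_y_tree(stem=10.0, branch=5.0)


@pytest.fixture
def binary_arbor():
    """Perfect binary tree with 8 leaves and a stem."""
    return make_binary_tree(depth=3)


@pytest.fixture
def random_arbors():
    """A reproducible collection of random trees for property tests."""
    return [random_arbor(seed, n_branches=int(3 + seed % 12)) for seed in range(40)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
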
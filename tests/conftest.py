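import numpy as np
import pytest

from wqfmtree.simulate import random_binary_rooted, random_unrooted_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_labels(n):
    return [f"t{i}" for i in range(n)]


@pytest.fixture
def random_tree_factory():
    def factory(n, seed, polytomy_prob=0.0):
        r = np.random.default_rng(seed)
        return random_unrooted_tree(make_labels(n), r, polytomy_prob)

    return factory


@pytest.fixture
def random_rooted_factory():
    def factory(n, seed):
        r = np.random.default_rng(seed)
        return random_binary_rooted(make_labels(n), r)

    return factory
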
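import numpy as np
import pytest

from phylosize import simulate_trait, simulate_yule_tree
from phylosize.tree import parse_newick


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return parse_newick("(A:1,B:1,C:1);")


@pytest.fixture
def balanced_four():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def random_tree_factory():
    """Seeded Yule trees for property tests."""

    def make(n_tips: int, seed: int, birth_rate: float = 0.2):
        return simulate_yule_tree(n_tips, birth_rate=birth_rate, seed=seed)

    return make


@pytest.fixture
def bm_dataset_factory(random_tree_factory):
    """(tree, trait) pairs simulated under BM."""

    def make(n_tips: int, seed: int, sigma2: float = 0.01):
        tree = random_tree_factory(n_tips, seed)
        x = simulate_trait(tree, "BM", sigma2=sigma2, z0=0.0, seed=seed + 10_000)
        return tree, x

    return make


def brute_force_covariance(tree):
    """Independent path-sum oracle: walk every tip pair's root paths."""
    labels = tree.tip_labels
    depth = tree.node_depths()
    n = len(labels)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                C[i, j] = depth[tree.tip_id(labels[i])]
            else:
                C[i, j] = depth[tree.mrca(labels[i], labels[j])]
    return C
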
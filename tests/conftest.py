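import dendropy
import numpy as np
import pytest

from aviamorph.io import LandmarkConfiguration
from aviamorph.phylo import phylo_covariance


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — the canonical worked example."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def three_taxon_cov(three_taxon_tree):
    return phylo_covariance(three_taxon_tree, ["A", "B", "C"])


@pytest.fixture
def star_tree_cov():
    tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
    return phylo_covariance(tree, ["A", "B", "C", "D"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_configuration(rng, n_landmarks=8, specimen_id="sp"):
    return LandmarkConfiguration(specimen_id, rng.normal(size=(n_landmarks, 3)))


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def random_tree(rng, n_tips):
    """Random-topology ultrametric-ish tree with random positive branch lengths."""
    from aviamorph.synthetic import simulate_yule_tree

    return simulate_yule_tree(n_tips, int(rng.integers(2 ** 31)))
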
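"""Shared fixtures: small trait matrices, random distance matrices, trees."""

import numpy as np
import pytest

from tadfd.traitspace import DistanceMatrix, FunctionalDendrogram, TraitMatrix


def random_distance_matrix(rng, n):
    """Tie-free random metric distances (Euclidean on random points)."""
    from scipy.spatial.distance import pdist, squareform
    X = rng.random((n, 5))
    return DistanceMatrix(tuple(f"s{i:02d}" for i in range(n)), squareform(pdist(X)))


def random_ultrametric_tree(rng, n):
    """Random binary merge tree with strictly increasing heights."""
    labels = tuple(f"s{i:02d}" for i in range(n))
    active = list(range(n))
    merges = []
    h = 0.0
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        h += rng.uniform(0.05, 0.3)
        merges.append((a, b, h))
        active.append(n + len(merges) - 1)
    return FunctionalDendrogram.from_merges(labels, merges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_traits():
    """3 species x (2 binary + 2 continuous), hand-built."""
    return TraitMatrix(
        species_ids=("a", "b", "c"),
        values=np.array([
            [0.0, 1.0, 0.0, 10.0],
            [1.0, 0.0, 1.0, 20.0],
            [0.0, 1.0, 0.5, 30.0],
        ]),
        trait_names=("b1", "b2", "c1", "c2"),
        trait_kinds=("binary", "binary", "continuous", "continuous"),
    )
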
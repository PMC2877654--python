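"""Gower distances, dendrogram construction, method selection, and FD."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from tadfd.traitspace import (
    DistanceMatrix,
    TraitMatrix,
    build_dendrogram,
    fd,
    gower_distance,
    select_clustering,
)

from conftest import random_distance_matrix, random_ultrametric_tree


def gower_brute(traits):
    """Element-by-element loop oracle for the Gower coefficient."""
    X = traits.values
    n, T = X.shape
    ranges = {}
    for j, kind in enumerate(traits.trait_kinds):
        if kind == "continuous":
            ranges[j] = X[:, j].max() - X[:, j].min()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for t in range(T):
                if traits.trait_kinds[t] == "binary":
                    acc += float(X[i, t] != X[j, t])
                else:
                    acc += abs(X[i, t] - X[j, t]) / ranges[t]
            d[i, j] = acc / T
    return d


def fd_path_union(tree, members):
    """Independent FD oracle: union of leaf-to-LCA edge paths."""
    idx = tree.leaf_indices(members)
    # ancestors of each member leaf
    paths = []
    for leaf in idx:
        path = [leaf]
        while tree.parent[path[-1]] != -1:
            path.append(tree.parent[path[-1]])
        paths.append(path)
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    lca = min(common, key=lambda v: tree.heights[v])
    edges = set()
    for p in paths:
        for v in p:
            if v == lca:
                break
            edges.add(v)
    return sum(tree.heights[tree.parent[v]] - tree.heights[v] for v in edges)


# ----------------------------------------------------------------------
# Gower
# ----------------------------------------------------------------------

class TestGower:
    def test_hand_built_matrix_matches_loop_oracle(self, tiny_traits):
        d = gower_distance(tiny_traits).d
        assert np.allclose(d, gower_brute(tiny_traits), atol=1e-12)

    def test_random_instances_match_loop_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(3, 10)
            nb, nc = rng.integers(1, 5, size=2)
            vals = np.hstack([
                rng.integers(0, 2, size=(n, nb)).astype(float),
                rng.random((n, nc)) * 10,
            ])
            tm = TraitMatrix(
                tuple(f"s{i}" for i in range(n)), vals,
                tuple(f"t{j}" for j in range(nb + nc)),
                ("binary",) * nb + ("continuous",) * nc,
            )
            assert np.allclose(gower_distance(tm).d, gower_brute(tm), atol=1e-12)

    def test_identical_rows_and_maximal_mismatch(self):
        # two species sharing every trait vs differing in every binary trait
        # and sitting at opposite ends of every continuous range
        vals = np.array([[0, 1, 0.0, 5.0], [0, 1, 0.0, 5.0], [1, 0, 1.0, 9.0]])
        tm = TraitMatrix(("a", "b", "c"), vals, ("b1", "b2", "c1", "c2"),
                         ("binary", "binary", "continuous", "continuous"))
        d = gower_distance(tm).d
        assert d[0, 1] == 0.0
        assert d[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()

    def test_all_binary_equals_hamming_fraction(self, rng):
        vals = rng.integers(0, 2, size=(6, 9)).astype(float)
        vals[0, 0] = 1 - vals[1, 0]  # ensure at least one mismatch exists
        tm = TraitMatrix(tuple("abcdef"), vals, tuple(f"t{j}" for j in range(9)),
                         ("binary",) * 9)
        d = gower_distance(tm).d
        for i, j in itertools.combinations(range(6), 2):
            assert d[i, j] == pytest.approx(np.mean(vals[i] != vals[j]), abs=1e-12)

    def test_invariant_under_species_and_trait_permutation(self, rng, tiny_traits):
        base = gower_distance(tiny_traits).d
        sp = rng.permutation(3)
        tr = rng.permutation(4)
        tm = TraitMatrix(
            tuple(tiny_traits.species_ids[i] for i in sp),
            tiny_traits.values[np.ix_(sp, tr)],
            tuple(tiny_traits.trait_names[j] for j in tr),
            tuple(tiny_traits.trait_kinds[j] for j in tr),
        )
        assert np.allclose(gower_distance(tm).d, base[np.ix_(sp, sp)], atol=1e-12)

    def test_zero_range_trait_is_named(self):
        vals = np.array([[0.0, 3.0], [1.0, 3.0]])
        tm = TraitMatrix(("a", "b"), vals, ("b1", "flat"),
                         ("binary", "continuous"))
        with pytest.raises(ValueError, match="flat"):
            gower_distance(tm)

    def test_non_binary_value_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            TraitMatrix(("a", "b"), np.array([[0.5], [1.0]]), ("b1",), ("binary",))

    def test_per_group_weights_equalise_ecological_traits(self):
        # one 2-column dummy-coded trait + one single-column trait:
        # grouped weighting halves the dummy columns' joint contribution
        vals = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        tm = TraitMatrix(("a", "b"), vals, ("g1_1", "g1_2", "g2"),
                         ("binary",) * 3, trait_groups=("g1", "g1", "g2"))
        flat = gower_distance(tm).d[0, 1]
        grouped = gower_distance(tm, per_group_weights=True).d[0, 1]
        assert flat == pytest.approx(1.0)
        assert grouped == pytest.approx(1.0)  # both ecological traits mismatch
        vals2 = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        tm2 = TraitMatrix(("a", "b"), vals2, ("g1_1", "g1_2", "g2"),
                          ("binary",) * 3, trait_groups=("g1", "g1", "g2"))
        assert gower_distance(tm2).d[0, 1] == pytest.approx(2 / 3)
        assert gower_distance(tm2, per_group_weights=True).d[0, 1] == pytest.approx(0.5)


# ----------------------------------------------------------------------
# Dendrograms
# ----------------------------------------------------------------------

class TestBuildDendrogram:
    def test_two_species_merge_at_half_distance(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = build_dendrogram(dm, "upgma")
        assert tree.heights[tree.root] == pytest.approx(0.2)
        assert tree.cophenetic()[0, 1] == pytest.approx(0.4)

    def test_four_species_hand_worked_upgma(self):
        # d(A,B)=0.2, d(C,D)=0.3, all cross distances 0.8
        d = np.full((4, 4), 0.8)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.2
        d[2, 3] = d[3, 2] = 0.3
        tree = build_dendrogram(DistanceMatrix(("A", "B", "C", "D"), d), "upgma")
        heights = sorted(tree.heights[4:])
        assert heights == pytest.approx([0.1, 0.15, 0.4])
        c = tree.cophenetic()
        assert c[0, 1] == pytest.approx(0.2)
        assert c[2, 3] == pytest.approx(0.3)
        assert c[0, 2] == pytest.approx(0.8)

    @pytest.mark.parametrize("ours,scipy_name", [
        ("single", "single"), ("complete", "complete"), ("upgma", "average"),
        ("wpgma", "weighted"), ("ward", "ward"),
    ])
    def test_cophenetic_matches_scipy_oracle(self, rng, ours, scipy_name):
        for _ in range(20):
            dm = random_distance_matrix(rng, int(rng.integers(4, 9)))
            c1 = build_dendrogram(dm, ours).cophenetic()
            c2 = squareform(cophenet(linkage(squareform(dm.d), scipy_name)))
            assert np.allclose(c1, c2, atol=1e-9)

    def test_cophenetic_matches_merge_height_rederivation(self, rng):
        # independent re-derivation: track cluster membership through merges
        for _ in range(20):
            dm = random_distance_matrix(rng, 8)
            tree = build_dendrogram(dm, "upgma")
            n = 8
            members = {i: {i} for i in range(n)}
            coph = np.zeros((n, n))
            for k, node in enumerate(sorted(tree.children)):
                a, b = tree.children[node]
                for i in members[a]:
                    for j in members[b]:
                        coph[i, j] = coph[j, i] = 2 * tree.heights[node]
                members[node] = members[a] | members[b]
            assert np.allclose(coph, tree.cophenetic(), atol=1e-12)

    def test_output_is_ultrametric(self, rng):
        for link in ("single", "complete", "upgma", "wpgma", "ward"):
            tree = build_dendrogram(random_distance_matrix(rng, 10), link)
            assert tree.is_ultrametric()

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), d)

    def test_deterministic_tie_break_is_lexicographic(self):
        # equilateral triangle: (a, b) must merge first
        d = np.full((3, 3), 0.6)
        np.fill_diagonal(d, 0.0)
        tree = build_dendrogram(DistanceMatrix(("c", "a", "b"), d), "upgma")
        first = min(tree.children)
        kids = tree.children[first]
        merged = sorted(tree.labels[k] for k in kids if k < 3)
        assert merged == ["a", "b"]


class TestSelectClustering:
    def test_ultrametric_input_recovered_by_upgma(self, rng):
        tree = random_ultrametric_tree(rng, 9)
        dm = DistanceMatrix(tree.labels, tree.cophenetic())
        sel = select_clustering(dm)
        assert sel.selected == "upgma"
        assert sel.criterion["upgma"] == pytest.approx(0.0, abs=1e-16)

    def test_selected_criterion_is_minimal(self, rng):
        for _ in range(10):
            dm = random_distance_matrix(rng, 8)
            sel = select_clustering(dm)
            assert sel.criterion[sel.selected] <= min(sel.criterion.values()) + 1e-12

    def test_single_candidate_is_selected(self, rng):
        dm = random_distance_matrix(rng, 6)
        sel = select_clustering(dm, candidates=("ward",))
        assert sel.selected == "ward"
        assert set(sel.criterion) == {"ward"}


# ----------------------------------------------------------------------
# FD
# ----------------------------------------------------------------------

class TestFD:
    def test_singleton_is_zero(self, rng):
        tree = random_ultrametric_tree(rng, 8)
        assert fd(tree, [tree.labels[3]]) == 0.0

    def test_pair_equals_cophenetic_distance(self, rng):
        tree = random_ultrametric_tree(rng, 8)
        c = tree.cophenetic()
        for i, j in [(0, 1), (2, 7), (4, 5)]:
            assert fd(tree, [tree.labels[i], tree.labels[j]]) == pytest.approx(c[i, j])

    def test_full_pool_equals_total_branch_length(self, rng):
        tree = random_ultrametric_tree(rng, 10)
        assert fd(tree, tree.labels) == pytest.approx(tree.total_branch_length())

    def test_random_subsets_match_path_union_oracle(self, rng):
        for _ in range(50):
            tree = random_ultrametric_tree(rng, int(rng.integers(3, 9)))
            n = tree.n_leaves
            size = int(rng.integers(1, n + 1))
            members = [tree.labels[i] for i in rng.choice(n, size, replace=False)]
            assert fd(tree, members) == pytest.approx(fd_path_union(tree, members),
                                                      abs=1e-12)

    def test_set_monotone_and_order_invariant(self, rng):
        tree = random_ultrametric_tree(rng, 9)
        labels = list(tree.labels)
        for _ in range(20):
            a = set(rng.choice(labels, size=int(rng.integers(1, 6)), replace=False))
            extra = set(rng.choice(labels, size=2, replace=False))
            b = a | extra
            assert fd(tree, a) <= fd(tree, b) + 1e-12
            shuffled = list(a)
            rng.shuffle(shuffled)
            assert fd(tree, shuffled) == pytest.approx(fd(tree, a))

    def test_errors_on_unknown_or_empty(self, rng):
        tree = random_ultrametric_tree(rng, 5)
        with pytest.raises(KeyError):
            fd(tree, ["nope"])
        with pytest.raises(ValueError):
            fd(tree, [])
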
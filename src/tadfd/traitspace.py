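"""Functional trait space: Gower distances, ultrametric dendrograms, and FD.

The continuous functional-diversity measure (FD) used throughout this
package is the dendrogram-based one of Petchey & Gaston: species are
placed in a trait space, pairwise dissimilarities are computed with
Gower's coefficient (the natural choice for mixed binary/continuous
trait matrices), the regional species pool is clustered into an
ultrametric dendrogram, and the FD of a community is the total branch
length of the minimal subtree connecting its member species.

One *regional* dendrogram is built from the full species pool and every
community is scored as a subtree of it.  This convention guarantees set
monotonicity (adding a species can never decrease FD) and makes
richness-controlled null models coherent, because observed and random
assemblages are measured on the same tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraitMatrix",
    "DistanceMatrix",
    "FunctionalDendrogram",
    "MethodSelection",
    "gower_distance",
    "build_dendrogram",
    "select_clustering",
    "fd",
    "LINKAGES",
]

BINARY = "binary"
CONTINUOUS = "continuous"

#: Canonical linkage names, in the fixed tie-preference order used by
#: :func:`select_clustering`.
LINKAGES = ("upgma", "wpgma", "complete", "single", "ward")

_LINKAGE_ALIASES = {
    "average": "upgma",
    "upgma": "upgma",
    "mcquitty": "wpgma",
    "wpgma": "wpgma",
    "complete": "complete",
    "single": "single",
    "ward": "ward",
}


def _normalize_linkage(name: str) -> str:
    key = str(name).strip().lower()
    if key not in _LINKAGE_ALIASES:
        raise ValueError(
            f"unknown linkage {name!r}; choose from {sorted(set(_LINKAGE_ALIASES))}"
        )
    return _LINKAGE_ALIASES[key]


@dataclass(frozen=True)
class TraitMatrix:
    """Species-by-trait values with per-trait kind metadata.

    Parameters
    ----------
    species_ids
        Ordered species labels (rows).
    values
        ``(n_species, n_traits)`` float array.  Binary columns must
        contain only 0/1; continuous columns may hold any finite value.
    trait_names
        Ordered trait labels (columns).
    trait_kinds
        ``"binary"`` or ``"continuous"`` per trait.
    trait_groups
        Optional group label per trait.  Binary columns obtained by
        dummy-coding one multi-state ecological trait (e.g. the six
        oral-disc shapes) share a group label; used only when Gower is
        asked to weight per ecological trait rather than per column.
    """

    species_ids: tuple
    values: np.ndarray
    trait_names: tuple
    trait_kinds: tuple
    trait_groups: tuple | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        object.__setattr__(self, "trait_kinds", tuple(self.trait_kinds))
        if self.trait_groups is not None:
            object.__setattr__(self, "trait_groups", tuple(self.trait_groups))
        if values.ndim != 2:
            raise ValueError("trait values must be a 2-D matrix")
        n_sp, n_tr = values.shape
        if n_sp < 2:
            raise ValueError("a trait matrix needs at least 2 species")
        if len(self.species_ids) != n_sp:
            raise ValueError("species_ids length does not match value rows")
        if len(set(self.species_ids)) != n_sp:
            raise ValueError("species_ids contains duplicates")
        if len(self.trait_names) != n_tr or len(self.trait_kinds) != n_tr:
            raise ValueError("trait metadata length does not match value columns")
        if self.trait_groups is not None and len(self.trait_groups) != n_tr:
            raise ValueError("trait_groups length does not match value columns")
        if not np.all(np.isfinite(values)):
            raise ValueError("trait matrix contains missing or non-finite values")
        for k in self.trait_kinds:
            if k not in (BINARY, CONTINUOUS):
                raise ValueError(f"unknown trait kind {k!r}")
        for j, kind in enumerate(self.trait_kinds):
            if kind == BINARY and not np.all(np.isin(values[:, j], (0.0, 1.0))):
                raise ValueError(
                    f"binary trait {self.trait_names[j]!r} has values outside {{0, 1}}"
                )

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def trait_ranges(self) -> dict:
        """Observed (min, max) per continuous trait over the full pool."""
        out = {}
        for j, kind in enumerate(self.trait_kinds):
            if kind == CONTINUOUS:
                col = self.values[:, j]
                out[self.trait_names[j]] = (float(col.min()), float(col.max()))
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with species labels."""

    labels: tuple
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite values")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("self-distances must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)


def gower_distance(traits: TraitMatrix, per_group_weights: bool = False) -> DistanceMatrix:
    """Gower dissimilarity on a mixed binary/continuous trait matrix.

    ``d(i, j) = sum_t w_t * delta_t(i, j) / sum_t w_t`` with
    ``delta_t = |x_it - x_jt| / range_t`` for continuous traits and the
    mismatch indicator for binary traits.  By default every column has
    weight 1 (the flat treatment of an 18-column trait table).  With
    ``per_group_weights=True`` the columns of each dummy-coded trait
    group share a total weight of 1, so each ecological trait counts
    equally regardless of how many binary states encode it.
    """
    X = traits.values
    n, T = X.shape
    deltas = np.empty((T, n, n))
    for j, kind in enumerate(traits.trait_kinds):
        col = X[:, j]
        if kind == CONTINUOUS:
            rng = col.max() - col.min()
            if rng <= 0:
                raise ValueError(
                    f"continuous trait {traits.trait_names[j]!r} has zero range "
                    "over the species pool; Gower scaling is undefined"
                )
            deltas[j] = np.abs(col[:, None] - col[None, :]) / rng
        else:
            deltas[j] = (col[:, None] != col[None, :]).astype(float)

    if per_group_weights:
        if traits.trait_groups is None:
            raise ValueError("per_group_weights requires trait_groups metadata")
        counts: dict = {}
        for g in traits.trait_groups:
            counts[g] = counts.get(g, 0) + 1
        w = np.array([1.0 / counts[g] for g in traits.trait_groups])
    else:
        w = np.ones(T)

    d = np.tensordot(w, deltas, axes=(0, 0)) / w.sum()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=traits.species_ids, d=d)


class FunctionalDendrogram:
    """Rooted ultrametric tree over a species pool, with branch lengths.

    Nodes ``0 .. n-1`` are leaves in label order; internal nodes are
    appended in merge order.  ``height[v]`` is the ultrametric height of
    node ``v`` (leaves at 0); the branch above ``v`` has length
    ``height[parent(v)] - height(v)``.  The cophenetic distance between
    two leaves is twice the height of their lowest common ancestor.
    """

    def __init__(self, labels, children: dict, heights, root: int):
        self.labels = tuple(labels)
        self.children = {int(k): tuple(int(c) for c in v) for k, v in children.items()}
        self.heights = np.asarray(heights, dtype=float)
        self.root = int(root)
        n = len(self.labels)
        K = len(self.heights)
        self._n_leaves = n
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        parent = np.full(K, -1, dtype=int)
        for v, kids in self.children.items():
            for c in kids:
                parent[c] = v
        self.parent = parent
        # leaf-membership matrix: leafsets[v, i] == leaf i descends from v
        L = np.zeros((K, n), dtype=bool)
        for i in range(n):
            L[i, i] = True
        for v in sorted(self.children):  # children always have smaller ids
            for c in self.children[v]:
                L[v] |= L[c]
        self.leafsets = L
        edge = np.zeros(K)
        nonroot = np.arange(K) != self.root
        edge[nonroot] = self.heights[parent[nonroot]] - self.heights[nonroot]
        if np.any(edge < -1e-9):
            raise ValueError("negative branch length: heights are not monotone")
        self.edge_lengths = np.clip(edge, 0.0, None)

    # ------------------------------------------------------------------
    @classmethod
    def from_merges(cls, labels, merges) -> "FunctionalDendrogram":
        """Build from a linkage-style merge list ``[(a, b, height), ...]``."""
        n = len(labels)
        children = {}
        heights = [0.0] * n
        for k, (a, b, h) in enumerate(merges):
            children[n + k] = (a, b)
            heights.append(float(h))
        return cls(labels, children, heights, root=n + len(merges) - 1)

    @property
    def n_leaves(self) -> int:
        return self._n_leaves

    def leaf_indices(self, members) -> np.ndarray:
        idx = []
        for m in members:
            if m not in self._index:
                raise KeyError(f"unknown species label {m!r}")
            idx.append(self._index[m])
        return np.asarray(idx, dtype=int)

    def total_branch_length(self) -> float:
        return float(self.edge_lengths.sum())

    def cophenetic(self) -> np.ndarray:
        """Leaf-by-leaf cophenetic distance matrix (2x LCA height)."""
        n = self._n_leaves
        c = np.zeros((n, n))
        for v in sorted(self.children):
            kids = self.children[v]
            for a, b in itertools.combinations(kids, 2):
                ia = np.flatnonzero(self.leafsets[a])
                ib = np.flatnonzero(self.leafsets[b])
                c[np.ix_(ia, ib)] = 2.0 * self.heights[v]
                c[np.ix_(ib, ia)] = 2.0 * self.heights[v]
        return c

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """Every leaf-to-root path length equals the root height."""
        depth = np.zeros(len(self.heights))
        order = sorted(self.children, reverse=True)
        for v in [self.root] + order:
            for c in self.children.get(v, ()):
                depth[c] = depth[v] + self.edge_lengths[c]
        leaf_depths = depth[: self._n_leaves]
        return bool(np.all(np.abs(leaf_depths - self.heights[self.root]) <= tol))

    # ------------------------------------------------------------------
    def fd_members(self, member_mask: np.ndarray) -> np.ndarray:
        """Vectorised FD for one or many communities.

        ``member_mask`` is ``(n_leaves,)`` or ``(n_leaves, m)`` boolean.
        A branch contributes iff it lies on a path between two member
        leaves, i.e. iff the set of member leaves below it is non-empty
        and proper — which truncates the subtree at the members' lowest
        common ancestor, so no branch above the LCA is counted.
        """
        M = np.asarray(member_mask, dtype=bool)
        squeeze = M.ndim == 1
        if squeeze:
            M = M[:, None]
        S = M.sum(axis=0)
        if np.any(S == 0):
            raise ValueError("empty community has no defined FD")
        counts = self.leafsets.astype(np.float64) @ M.astype(np.float64)
        inside = (counts > 0.5) & (counts < S[None, :] - 0.5)
        out = self.edge_lengths @ inside
        return float(out[0]) if squeeze else out

    def to_newick(self, digits: int = 10) -> str:
        def rec(v):
            if v < self._n_leaves:
                name = str(self.labels[v])
            else:
                name = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            bl = self.edge_lengths[v] if v != self.root else 0.0
            return f"{name}:{bl:.{digits}g}" if v != self.root else name
        return rec(self.root) + ";"


def fd(tree: FunctionalDendrogram, members) -> float:
    """FD of a community: branch length of the minimal spanning subtree.

    The subtree is truncated at the members' lowest common ancestor;
    a singleton community has FD 0 and the full pool recovers the total
    branch length of the regional dendrogram.
    """
    members = list(members)
    if len(members) == 0:
        raise ValueError("empty community has no defined FD")
    idx = tree.leaf_indices(members)
    mask = np.zeros(tree.n_leaves, dtype=bool)
    mask[idx] = True
    return tree.fd_members(mask)


# ----------------------------------------------------------------------
# Agglomerative clustering with deterministic tie-breaking
# ----------------------------------------------------------------------

def build_dendrogram(dist: DistanceMatrix, linkage: str = "upgma") -> FunctionalDendrogram:
    """Agglomerate a distance matrix into an ultrametric dendrogram.

    Supported linkages: single, complete, UPGMA (average), WPGMA
    (McQuitty), Ward.  Merge heights are half the inter-cluster distance
    at merge, so the cophenetic distance between leaves equals the
    linkage distance of the merge that joined them (for UPGMA, the
    average original distance between the two clusters).  Ward operates
    on squared distances; its heights are the square root of the merge
    criterion, halved, which keeps the output ultrametric.

    Ties in the minimal inter-cluster distance are broken by the
    lexicographically smallest pair of cluster representatives (a
    cluster is represented by its smallest member label), making trees
    bit-reproducible across platforms.
    """
    method = _normalize_linkage(linkage)
    labels = dist.labels
    n = len(labels)
    squared = method == "ward"
    M = dist.d.astype(float) ** 2 if squared else dist.d.astype(float).copy()

    node_of = list(range(n))          # active slot -> tree node id
    reps = [str(lab) for lab in labels]
    sizes = [1] * n
    active = list(range(n))           # active slots (indices into M rows)
    merges = []
    next_node = n
    TOL = 1e-12

    while len(active) > 1:
        # minimal current distance with lexicographic tie-break
        best = None
        best_d = np.inf
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                dij = M[a, b]
                if dij < best_d - TOL:
                    best, best_d = (a, b), dij
                elif abs(dij - best_d) <= TOL:
                    key_new = tuple(sorted((reps[a], reps[b])))
                    key_old = tuple(sorted((reps[best[0]], reps[best[1]])))
                    if key_new < key_old:
                        best = (a, b)
        a, b = best
        raw = np.sqrt(M[a, b]) if squared else M[a, b]
        h = raw / 2.0
        if merges:  # guard: monotone heights (all these linkages are monotone)
            h = max(h, merges[-1][2])
        merges.append((node_of[a], node_of[b], h))

        na, nb = sizes[a], sizes[b]
        for k in active:
            if k in (a, b):
                continue
            dka, dkb, dab = M[k, a], M[k, b], M[a, b]
            if method == "single":
                dnew = min(dka, dkb)
            elif method == "complete":
                dnew = max(dka, dkb)
            elif method == "upgma":
                dnew = (na * dka + nb * dkb) / (na + nb)
            elif method == "wpgma":
                dnew = 0.5 * (dka + dkb)
            else:  # ward, on squared distances
                nk = sizes[k]
                dnew = ((na + nk) * dka + (nb + nk) * dkb - nk * dab) / (na + nb + nk)
            M[a, k] = M[k, a] = dnew
        sizes[a] = na + nb
        reps[a] = min(reps[a], reps[b])
        node_of[a] = next_node
        next_node += 1
        active.remove(b)

    return FunctionalDendrogram.from_merges(labels, merges)


@dataclass(frozen=True)
class MethodSelection:
    """Result of the automated clustering-method selection.

    ``criterion`` maps each candidate linkage to the sum of squared
    differences between the input distances and the candidate tree's
    cophenetic distances; the selected linkage minimises it, with ties
    resolved by a fixed preference order (UPGMA first).
    """

    candidates: tuple
    criterion: dict
    selected: str
    trees: dict = field(repr=False, default=None)

    @property
    def tree(self) -> FunctionalDendrogram:
        return self.trees[self.selected]


def select_clustering(dist: DistanceMatrix, candidates=LINKAGES) -> MethodSelection:
    """Pick the linkage whose ultrametric tree best preserves the distances.

    For each candidate the fit criterion is
    ``sum_{i<j} (d(i,j) - c(i,j))**2`` where ``c`` is the cophenetic
    matrix of the candidate dendrogram.  A distance matrix that is
    already ultrametric is recovered exactly by UPGMA (criterion 0).
    """
    cand = tuple(_normalize_linkage(c) for c in candidates)
    if len(cand) == 0:
        raise ValueError("need at least one candidate linkage")
    iu = np.triu_indices(dist.n, k=1)
    crit = {}
    trees = {}
    for c in cand:
        tree = build_dendrogram(dist, c)
        coph = tree.cophenetic()
        crit[c] = float(np.sum((dist.d[iu] - coph[iu]) ** 2))
        trees[c] = tree
    best = min(crit.values())
    TOL = 1e-12
    ordered = [c for c in LINKAGES if c in cand] + [c for c in cand if c not in LINKAGES]
    selected = next(c for c in ordered if crit[c] <= best + TOL)
    return MethodSelection(candidates=cand, criterion=crit, selected=selected, trees=trees)
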
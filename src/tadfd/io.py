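"""Plain-text readers and writers for the pipeline's artifacts.

All tabular artifacts are tab-separated text with a header row; trait
kind/group metadata travels in a sidecar table next to the trait
matrix; dendrograms are written as Newick strings with branch lengths.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .tables import CommunityTable, HabitatTable
from .traitspace import DistanceMatrix, FunctionalDendrogram, TraitMatrix

__all__ = [
    "write_trait_matrix", "read_trait_matrix",
    "write_community_table", "read_community_table",
    "write_habitat_table", "read_habitat_table",
    "write_distance_matrix",
    "write_newick", "read_newick",
]

SEP = "\t"


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta")


def write_trait_matrix(traits: TraitMatrix, path) -> None:
    """Write species x trait values plus a trait-metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(traits.values, index=list(traits.species_ids),
                      columns=list(traits.trait_names)).rename_axis("species")
    df.to_csv(path, sep=SEP)
    groups = traits.trait_groups or [""] * traits.n_traits
    meta = pd.DataFrame({
        "trait": list(traits.trait_names),
        "kind": list(traits.trait_kinds),
        "group": list(groups),
    })
    meta.to_csv(_sidecar(path), sep=SEP, index=False)


def read_trait_matrix(path) -> TraitMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, index_col=0)
    meta = pd.read_csv(_sidecar(path), sep=SEP).fillna("")
    if list(meta["trait"]) != list(df.columns):
        raise ValueError("trait sidecar does not match trait matrix columns")
    groups = tuple(meta["group"]) if meta["group"].astype(bool).any() else None
    return TraitMatrix(
        species_ids=tuple(df.index.astype(str)),
        values=df.to_numpy(dtype=float),
        trait_names=tuple(df.columns),
        trait_kinds=tuple(meta["kind"]),
        trait_groups=groups,
    )


def write_community_table(communities: CommunityTable, path) -> None:
    communities.to_frame().to_csv(Path(path), sep=SEP)


def read_community_table(path) -> CommunityTable:
    df = pd.read_csv(Path(path), sep=SEP, index_col=0)
    return CommunityTable(
        site_ids=tuple(df.index.astype(str)),
        species_ids=tuple(df.columns),
        presence=df.to_numpy(),
    )


def write_habitat_table(habitat: HabitatTable, path) -> None:
    habitat.df.to_csv(Path(path), sep=SEP)


def read_habitat_table(path) -> HabitatTable:
    df = pd.read_csv(Path(path), sep=SEP, index_col=0)
    return HabitatTable(df=df)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    pd.DataFrame(dist.d, index=list(dist.labels), columns=list(dist.labels)) \
        .rename_axis("species").to_csv(Path(path), sep=SEP)


def write_newick(tree: FunctionalDendrogram, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path_or_string, tol: float = 1e-6) -> FunctionalDendrogram:
    """Load an ultrametric dendrogram from Newick with branch lengths.

    Node heights are reconstructed from root-to-leaf path lengths; the
    input must be ultrametric within ``tol``.
    """
    src = str(path_or_string)
    if Path(src).exists():
        t = dendropy.Tree.get(path=src, schema="newick")
    else:
        t = dendropy.Tree.get(data=src, schema="newick")
    leaves = [lf for lf in t.leaf_node_iter()]
    labels = sorted(str(lf.taxon.label) for lf in leaves)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    # depth from root, then height = max leaf depth - depth
    depth = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaf_depths = [depth[lf] for lf in leaves]
    root_h = max(leaf_depths)
    if max(leaf_depths) - min(leaf_depths) > tol:
        raise ValueError("tree is not ultrametric; cannot interpret as a dendrogram")

    children: dict = {}
    heights = [0.0] * n
    ids = {}
    next_id = n
    for node in t.postorder_node_iter():
        if node.is_leaf():
            ids[node] = index[str(node.taxon.label)]
        else:
            kid_ids = tuple(ids[c] for c in node.child_nodes())
            ids[node] = next_id
            children[next_id] = kid_ids
            heights.append(max(root_h - depth[node], 0.0))
            next_id += 1
    return FunctionalDendrogram(labels, children, heights, root=ids[t.seed_node])
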
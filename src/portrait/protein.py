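"""Protein (RPPA) layer: similarity (score component D) and hierarchical
clustering of samples by their (phospho-)protein profiles.

Clustering uses agglomerative linkage on either 1 - Pearson correlation or
Euclidean distance between sample columns; the resulting dendrogram can be
cut into k flat clusters or exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .correlate import PairwiseCorrelationTable, pairwise_correlation
from .errors import ValidationError
from .io import LabeledMatrix

__all__ = ["protein_similarity", "hierarchical_cluster", "cut_clusters", "Dendrogram"]


def protein_similarity(
    cells: LabeledMatrix,
    tumors: LabeledMatrix,
    subtype_map: dict[str, str] | None = None,
) -> PairwiseCorrelationTable:
    """Pearson r per (cell, tumor) pair over shared proteins.

    With a ``subtype_map`` only same-subtype pairs are computed; the rest are
    left missing (the subtype-matched view of the layer).
    """
    table = pairwise_correlation(cells, tumors, layer="protein")
    if subtype_map is not None:
        df = table.df.copy()
        for cell in df.index:
            label = subtype_map.get(cell)
            for tumor in df.columns:
                if subtype_map.get(tumor) != label:
                    df.at[cell, tumor] = np.nan
        table = PairwiseCorrelationTable(df, layer=table.layer,
                                         features_used=table.features_used)
    return table


@dataclass
class Dendrogram:
    """SciPy linkage matrix plus the leaf sample ids (input order)."""

    linkage: np.ndarray
    leaves: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _condensed_distance(matrix: LabeledMatrix, distance: str) -> np.ndarray:
    x = matrix.data.to_numpy(dtype=float).T  # samples x features
    if distance == "euclidean":
        return pdist(x, metric="euclidean")
    if distance == "one_minus_pearson":
        sd = x.std(axis=1)
        if (sd == 0).any():
            bad = matrix.sample_ids[int(np.flatnonzero(sd == 0)[0])]
            raise ValidationError(
                f"sample {bad!r} is constant: correlation distance undefined"
            )
        return pdist(x, metric="correlation")  # = 1 - Pearson r
    raise ValueError(f"unknown distance {distance!r}")


def hierarchical_cluster(
    matrix: LabeledMatrix,
    linkage: str = "average",
    distance: str = "one_minus_pearson",
) -> Dendrogram:
    """Agglomerative clustering of the samples (columns) of ``matrix``."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValidationError("clustering needs >= 2 samples and >= 2 features")
    d = _condensed_distance(matrix, distance)
    z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(z, list(matrix.sample_ids))


def cut_clusters(tree: Dendrogram, k: int) -> dict[str, int]:
    """Flat partition into k clusters by removing the k-1 highest merges."""
    n = len(tree.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    labels = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return dict(zip(tree.leaves, (int(v) for v in labels)))


def cophenetic_distance(tree: Dendrogram) -> pd.DataFrame:
    """Pairwise merge heights between leaves (useful for tree diagnostics)."""
    d = squareform(hierarchy.cophenet(tree.linkage))
    return pd.DataFrame(d, index=tree.leaves, columns=tree.leaves)


def to_newick(tree: Dendrogram) -> str:
    """Newick export; branch lengths are height differences between merges."""
    root = hierarchy.to_tree(tree.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.leaves[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(root, root.dist) + ";"
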
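"""Subject-to-subject similarity: Spearman correlation, Euclidean
distances, hierarchical clustering, and Manhattan distance on Boolean
profiles.

Counts are log(count+1)-transformed for clustering by default — the
pseudocount of 1 maps absence to exactly 0 — while the Spearman matrix
is rank-based and therefore invariant to any strictly monotone
transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .data import SpectralCountMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "spearman_matrix",
    "euclidean_distance_matrix",
    "hierarchical_clustering",
    "manhattan_distance",
]

LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric subject x subject distances with zero diagonal."""

    values: pd.DataFrame
    metric_name: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over subjects.

    ``merges`` lists (node_a, node_b, height) triples in merge order;
    leaves are numbered 0..n-1 in ``leaf_ids`` order and internal nodes
    continue from n, as in the scipy linkage encoding.
    """

    merges: list[tuple[int, int, float]]
    leaf_ids: list[str]
    linkage_name: str
    _linkage: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self._linkage)
        return [self.leaf_ids[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Cut into ``k`` flat clusters; returns subject -> cluster label."""
        labels = hierarchy.fcluster(self._linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaf_ids, name="cluster")

    def to_newick(self) -> str:
        """Serialise the tree, with branch lengths, in Newick format."""
        tree = hierarchy.to_tree(self._linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return render(tree, tree.dist) + ";"


def spearman_matrix(matrix: SpectralCountMatrix) -> pd.DataFrame:
    """Spearman rank-correlation matrix between subjects.

    Ties receive average ranks.  A subject whose counts are constant has
    no rank variance; its correlations are undefined and reported as NaN
    with a warning.
    """
    counts = matrix.counts
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 proteins for rank correlations")
    constant = counts.nunique(axis=0) <= 1
    if constant.any():
        warnings.warn(
            f"zero-variance subject vector(s) {list(counts.columns[constant])}: "
            "Spearman correlation undefined, reported as NaN",
            stacklevel=2,
        )
    # Spearman = Pearson on average ranks; np.corrcoef keeps the matrix
    # form for any number of subjects (scipy collapses the 2-subject case)
    ranks = counts.rank(axis=0, method="average").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks.T)
    np.fill_diagonal(rho, 1.0)
    rho[constant.to_numpy(), :] = np.nan
    rho[:, constant.to_numpy()] = np.nan
    return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)


def euclidean_distance_matrix(
    matrix: SpectralCountMatrix, log_transform: bool = True
) -> DistanceMatrix:
    """Euclidean distances between subjects' (optionally log1p) count vectors."""
    x = matrix.counts.to_numpy(dtype=float).T
    if log_transform:
        x = np.log1p(x)
    d = squareform(pdist(x, metric="euclidean"))
    name = "euclidean(log1p)" if log_transform else "euclidean"
    return DistanceMatrix(
        pd.DataFrame(d, index=matrix.counts.columns, columns=matrix.counts.columns), name
    )


def hierarchical_clustering(dist: DistanceMatrix, linkage_name: str = "average") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Deterministic for a fixed input; supported linkages are
    single/complete/average/ward.
    """
    if linkage_name not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage_name!r}; supported: {', '.join(LINKAGES)}")
    z = hierarchy.linkage(dist.condensed(), method=linkage_name)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(merges, dist.subject_ids, linkage_name, _linkage=z)


def manhattan_distance(profile_a, profile_b) -> int:
    """L1 distance between two profiles; on Boolean profiles this is the
    number of proteins whose presence status differs."""
    a = np.asarray(profile_a)
    b = np.asarray(profile_b)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return int(np.abs(a.astype(np.int64) - b.astype(np.int64)).sum())
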
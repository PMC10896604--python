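"""Unsupervised sample-structure views: PCA and hierarchical clustering.

Both operate on a transformed table (log-autoscaled, missing values
imputed upstream).  PCA is computed by SVD of the centered samples x
features matrix with a deterministic sign convention (the
largest-magnitude element of each loading vector is positive), so results
are reproducible across runs and linear-algebra backends.  HCA defaults to
Ward linkage on Euclidean distances; cutting the tree at two clusters
gives a sample partition whose agreement with the GR/PR labels measures
how strongly the omics layer separates the response groups.  Supervised
clustering "by DAPs/DAMs" is the same operation on the table restricted to
the significant feature subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tables import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame               # samples x components
    loadings: pd.DataFrame             # features x components
    explained_variance_fraction: np.ndarray


@dataclass
class HcaResult:
    linkage_matrix: np.ndarray         # scipy (n-1) x 4 merge tree
    leaf_order: list[str]
    sample_ids: list[str]
    linkage: str
    distance: str

    def cut(self, n_clusters: int = 2) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)
        ids = self.sample_ids

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def pca(table: FeatureTable, n_components: int = 5) -> PcaResult:
    """PCA of samples over features via SVD of the centered matrix."""
    X = table.values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("pca requires an imputed table (no missing values)")
    n, p = X.shape
    max_comp = min(n, p)
    if n_components > max_comp:
        logger.warning("n_components %d > min(dim) %d; truncated", n_components, max_comp)
        n_components = max_comp
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|.| element of each loading vector positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{i+1}" for i in range(n_components)]
    scores = pd.DataFrame(u[:, :n_components] * s[:n_components],
                          index=table.sample_ids, columns=comps)
    loadings = pd.DataFrame(vt[:n_components].T, index=table.feature_ids, columns=comps)
    return PcaResult(scores, loadings, frac[:n_components])


_LINKAGES = {"ward", "average", "complete", "single"}
_DISTANCES = {"euclidean", "cityblock", "correlation", "cosine"}


def hca(table: FeatureTable, distance: str = "euclidean", linkage: str = "ward") -> HcaResult:
    """Agglomerative clustering of samples on the transformed table."""
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(_LINKAGES)}")
    if distance not in _DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; choose from {sorted(_DISTANCES)}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    X = table.values.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("hca requires an imputed table (no missing values)")
    Z = hierarchy.linkage(pdist(X, metric=distance), method=linkage)
    order = hierarchy.leaves_list(Z)
    ids = table.sample_ids
    return HcaResult(Z, [ids[i] for i in order], ids, linkage, distance)


def cluster_agreement(clusters: pd.Series, groups: pd.Series) -> float:
    """Best-matching agreement between a 2-cluster cut and the group labels."""
    groups = groups.reindex(clusters.index)
    g = (groups == sorted(groups.unique())[0]).astype(int)
    c = (clusters == clusters.unique()[0]).astype(int)
    agree = (g == c).mean()
    return float(max(agree, 1.0 - agree))
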
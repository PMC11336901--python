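"""ITH phenotyping: highly variable genes, Ward clustering, h/m/l labels.

ROIs are grouped into three transcript-defined clusters from the top
variable genes and the clusters are named by their heterogeneity level:
the cluster with the highest median DEPTH score is the high-ITH (h-ITH)
phenotype, the middle one medium-ITH (m-ITH), the lowest low-ITH (l-ITH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .heterogeneity import HeterogeneityScores

__all__ = [
    "PhenotypeAssignment",
    "select_hvg",
    "cluster_rois",
    "label_ith_phenotypes",
    "embed_2d",
]

PHENOTYPE_ORDER = ("h-ITH", "m-ITH", "l-ITH")


@dataclass
class PhenotypeAssignment:
    hvg: list[str]
    cluster: pd.Series  # roi -> cluster index (1-based)
    phenotype: pd.Series  # roi -> {h-ITH, m-ITH, l-ITH}
    linkage_summary: np.ndarray  # merge heights from the dendrogram


def select_hvg(matrix: pd.DataFrame, n_top: int = 200, n_components: int = 10) -> list[str]:
    """Rank genes by variance-weighted squared PCA loadings; return the top.

    For each gene the score is the sum over the top ``n_components``
    principal components of (loading^2 x component variance) — the part of
    the gene's variance captured by the leading eigenvectors.  Ties break
    deterministically by gene symbol; zero-variance genes score 0.
    """
    n_genes, n_rois = matrix.shape
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds available genes ({n_genes})")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    k = min(n_components, n_rois - 1, n_genes)
    X = matrix.to_numpy(dtype=float).T  # ROIs as samples
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    score = (pca.components_**2 * pca.explained_variance_[:, None]).sum(axis=0)
    ranked = sorted(zip(-score, matrix.index))  # descending score, symbol tiebreak
    return [g for _, g in ranked[:n_top]]


def cluster_rois(matrix: pd.DataFrame, k: int = 3, linkage: str = "ward",
                 standardize: bool = True) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of ROIs on (standardized) HVG profiles.

    Ward's criterion on Euclidean distances (the ward.D2 convention);
    returns (roi -> 1-based cluster index, linkage merge heights).
    """
    n_rois = matrix.shape[1]
    if not 1 <= k <= n_rois:
        raise ValueError(f"k must be in [1, {n_rois}]")
    if linkage != "ward":
        raise ValueError(f"unsupported linkage {linkage!r}")
    X = matrix.to_numpy(dtype=float).T
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    Z = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns, name="cluster"), Z[:, 2]


def label_ith_phenotypes(
    cluster: pd.Series, depth: HeterogeneityScores | pd.Series
) -> pd.Series:
    """Name clusters h-/m-/l-ITH by descending median DEPTH score.

    Ties on the median break by mean DEPTH, then by smallest cluster index.
    Two clusters are labeled {h-ITH, l-ITH} with a warning; more than three
    clusters are an error.
    """
    depth = depth.depth if isinstance(depth, HeterogeneityScores) else depth
    ids = sorted(cluster.unique())
    k = len(ids)
    if k > 3:
        raise ValueError(f"phenotype labeling needs <=3 clusters, got {k}")
    stats = []
    for cid in ids:
        d = depth[cluster.index[cluster == cid]]
        stats.append((-d.median(), -d.mean(), cid))
    ordered = [cid for *_, cid in sorted(stats)]
    if k == 3:
        names = PHENOTYPE_ORDER
    elif k == 2:
        warnings.warn("only 2 clusters: labeling restricted to {h-ITH, l-ITH}")
        names = ("h-ITH", "l-ITH")
    else:
        names = ("h-ITH",)
    mapping = dict(zip(ordered, names))
    return cluster.map(mapping).rename("phenotype")


def embed_2d(matrix: pd.DataFrame, seed: int = 0, perplexity: float = 10.0) -> pd.DataFrame:
    """t-SNE projection of ROI profiles to 2D, for visualization only.

    Deterministic for a fixed seed; clustering never consumes these
    coordinates.
    """
    n_rois = matrix.shape[1]
    if n_rois <= perplexity:
        raise ValueError(f"need n_ROIs > perplexity ({perplexity}), got {n_rois}")
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = ts.fit_transform(matrix.to_numpy(dtype=float).T)
    return pd.DataFrame(coords, index=matrix.columns, columns=["tsne1", "tsne2"])


def assign_phenotypes(
    matrix: pd.DataFrame,
    depth: HeterogeneityScores | pd.Series,
    n_hvg: int = 200,
    k: int = 3,
    n_components: int = 10,
) -> PhenotypeAssignment:
    """Full phenotyping pass: HVG selection, Ward clustering, ITH labels."""
    hvg = select_hvg(matrix, n_top=n_hvg, n_components=n_components)
    cluster, heights = cluster_rois(matrix.loc[hvg], k=k)
    phenotype = label_ith_phenotypes(cluster, depth)
    return PhenotypeAssignment(
        hvg=hvg, cluster=cluster, phenotype=phenotype, linkage_summary=heights
    )
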
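"""Clustering and overview statistics for abundance/score profiles.

Profiles (complex scores or protein abundances, items x species) are
normally converted to relative profiles — each row divided by its row
sum — before clustering, so that clusters group species *patterns* rather
than absolute magnitudes. Two clusterings are offered:

* ``ward_cut``: agglomerative Ward linkage (minimum increase in
  within-cluster sum of squares, on Euclidean distances; the "ward.D2"
  contract) with the dendrogram cut to exactly k clusters.
* ``kmeans_profiles``: best-of-n_init k-means with k-means++ seeding.

``pearson_matrix`` and ``pca_overview`` provide the species-level
similarity overview.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .datatypes import ClusterAssignment, DataModelError


def relative_profile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its row sum (missing cells treated as zero)."""
    filled = matrix.fillna(0.0)
    sums = filled.sum(axis=1)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise DataModelError(f"all-zero profile row(s): {list(zero[:3])}")
    return filled.div(sums, axis=0)


def ward_cut(matrix: pd.DataFrame, k: int) -> ClusterAssignment:
    """Ward hierarchical clustering of rows, dendrogram cut at k clusters."""
    n = len(matrix)
    if k > n:
        raise DataModelError(f"k={k} exceeds the {n} items available")
    x = matrix.fillna(0.0).to_numpy(dtype=float)
    if n == 1:
        labels = np.array([1])
    else:
        z = linkage(x, method="ward")
        labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels.astype(int), index=matrix.index),
        k=k,
        method="ward",
    )


def kmeans_profiles(
    matrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 25
) -> ClusterAssignment:
    """Best-of-``n_init`` k-means over rows; reproducible for a fixed seed."""
    n = len(matrix)
    if k > n:
        raise DataModelError(f"k={k} exceeds the {n} items available")
    x = matrix.fillna(0.0).to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x) + 1
    return ClusterAssignment(
        labels=pd.Series(labels.astype(int), index=matrix.index),
        k=k,
        method="kmeans",
        seed=seed,
    )


def pearson_matrix(matrix: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Species x species Pearson correlations over rows detected in both.

    Pairs with fewer than ``min_shared`` shared detected rows, or with a
    constant column, are flagged undefined (NaN). The diagonal is 1.
    """
    species = list(matrix.columns)
    if len(species) < 2:
        raise DataModelError("need at least two species")
    out = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            both = matrix[a].notna() & matrix[b].notna()
            if both.sum() < min_shared:
                r = np.nan
            else:
                xa = matrix.loc[both, a].to_numpy(dtype=float)
                xb = matrix.loc[both, b].to_numpy(dtype=float)
                if np.std(xa) == 0 or np.std(xb) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(xa, xb)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def pca_overview(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of rows: coordinates plus variance-explained fractions."""
    x = matrix.fillna(0.0).to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise DataModelError("PCA needs at least two items and two species")
    if np.allclose(x, x[0]):
        raise DataModelError("constant matrix has no principal components")
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return (
        pd.DataFrame(coords, index=matrix.index, columns=cols),
        pca.explained_variance_ratio_,
    )
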
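"""Profile clustering: mean-standardised heat-map matrices and
Pearson-similarity + UPGMA dendrograms.

One engine serves both uses in the analysis: clustering genes selected by
the ANOVA screen (rows of a mean-standardised log2 matrix) and clustering
whole sample/fingerprint profiles.  Similarities are Pearson correlations;
the similarity-to-distance conversion is d = 1 - r; linkage is UPGMA
(size-weighted average), whose merge heights are nondecreasing and whose
cophenetic distances form an ultrametric.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "standardize_by_gene_mean",
    "pearson_similarity",
    "upgma",
    "cluster_gene_rows",
    "Dendrogram",
]


def standardize_by_gene_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's across-column mean (log2 differences vs mean)."""
    out = matrix.sub(matrix.mean(axis=1), axis=0)
    out.attrs["scale"] = "log2"
    return out


def pearson_similarity(profiles) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of row profiles.

    ``profiles`` is an array or DataFrame with one profile per row.  A
    zero-variance profile makes the coefficient undefined and raises.
    """
    if isinstance(profiles, pd.DataFrame):
        labels = profiles.index
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        labels = pd.RangeIndex(len(X))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two equal-length profiles")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(labels[np.flatnonzero(sd == 0)])
        raise ValueError(f"zero-variance profiles: {bad}")
    S = np.corrcoef(X)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=labels, columns=labels)


@dataclasses.dataclass
class Dendrogram:
    """UPGMA tree: leaf labels plus the ordered merge list.

    ``linkage`` is a scipy linkage matrix; ``merges`` lists
    (cluster_a, cluster_b, height, size) in merge order, clusters numbered
    scipy-style (leaves 0..n-1, merge i creates cluster n+i).
    """

    labels: list
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(row[0]), int(row[1]), float(row[2]), int(row[3]))
            for row in self.linkage
        ]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def leaf_clusters(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )


def upgma(similarity: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram from a Pearson-similarity matrix (d = 1 - r)."""
    S = (
        similarity.to_numpy(dtype=float)
        if isinstance(similarity, pd.DataFrame)
        else np.asarray(similarity, dtype=float)
    )
    labels = (
        list(similarity.index)
        if isinstance(similarity, pd.DataFrame)
        else list(range(len(S)))
    )
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(labels=labels, linkage=Z)


def cluster_gene_rows(
    matrix: pd.DataFrame, linkage_method: str = "average"
) -> Dendrogram:
    """Cluster gene rows of a (mean-standardised) matrix by 1 - Pearson r.

    The default UPGMA linkage matches the sample-profile engine; other
    scipy linkages are accepted for exploratory use.
    """
    S = pearson_similarity(matrix)
    D = 1.0 - S.to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    return Dendrogram(labels=list(matrix.index), linkage=Z)
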
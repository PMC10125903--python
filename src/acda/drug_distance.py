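"""Drug-drug cophenetic distances from monotherapy sensitivity.

The drug-similarity measure is built in three stages:

1. project each drug's response vector across models to pairwise cosine
   similarity, giving an n x n matrix ``A``;
2. take the Euclidean distance between rows of ``A`` (each drug described by
   its similarity profile to every other drug), giving the distance matrix
   ``M`` that Ward linkage requires;
3. hierarchically cluster ``M`` with Ward linkage and read off the cophenetic
   distance -- the merge height at which two drugs first join a common
   cluster.  Cophenetic distances are ultrametric by construction.

Matrices are returned as square, symmetric :class:`pandas.DataFrame` objects
labeled by drug id on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .data_model import MonotherapyMatrix, ValidationError

__all__ = [
    "DegenerateVectorError",
    "LinkageTree",
    "cosine_similarity_matrix",
    "impute_missing_similarity",
    "distance_of_similarity_profiles",
    "ward_cophenetic",
    "drug_drug_distance",
]

#: minimum number of models two drugs must share for a trusted cosine value
DEFAULT_MIN_OVERLAP = 3


class DegenerateVectorError(ValueError):
    """A drug's observed response vector has zero norm; cosine is undefined."""


@dataclass(frozen=True)
class LinkageTree:
    """Ward merge tree over drugs.

    ``linkage`` is the standard (n-1) x 4 agglomeration matrix
    (left cluster, right cluster, merge height, merged size); ``ids`` gives
    the leaf labels in input order and ``leaf_order`` the left-to-right leaf
    sequence of the plotted dendrogram.
    """

    linkage: np.ndarray
    ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels from cutting the tree into ``n_clusters``."""
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=list(self.ids), name="cluster")


def cosine_similarity_matrix(
    monotherapy: MonotherapyMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> pd.DataFrame:
    """Pairwise cosine similarity of drug response vectors.

    Each entry (i, j) is the cosine of the two drugs' sensitivity vectors
    restricted to models observed in both.  Cosine uses raw (uncentered)
    values; no z-scoring.  Pairs sharing fewer than ``min_overlap`` models
    (or with a zero-norm restricted vector) are NaN, to be imputed before
    the Euclidean step.  The diagonal is 1.
    """
    df = monotherapy.df
    values = df.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    zero_norm = [
        drug
        for drug, row, mask in zip(df.index, values, observed)
        if not np.any(row[mask] != 0)
    ]
    if zero_norm:
        raise DegenerateVectorError(
            f"all-zero observed response vector for drug(s): {zero_norm}"
        )
    n = len(df)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = observed[i] & observed[j]
            s = np.nan
            if both.sum() >= min_overlap:
                xi, xj = values[i, both], values[j, both]
                denom = np.linalg.norm(xi) * np.linalg.norm(xj)
                if denom > 0:
                    s = float(np.dot(xi, xj) / denom)
            sim[i, j] = sim[j, i] = s
    return pd.DataFrame(sim, index=df.index.copy(), columns=df.index.copy())


def impute_missing_similarity(similarity: pd.DataFrame) -> pd.DataFrame:
    """Replace NaN similarities with the minimum observed off-diagonal value.

    Insufficient overlap is treated as maximal dissimilarity (the
    distance-equivalent of the largest observed gap), which keeps such pairs
    far apart in the subsequent clustering without inventing structure.
    """
    values = similarity.to_numpy(dtype=float).copy()
    off = ~np.eye(len(values), dtype=bool)
    observed = off & ~np.isnan(values)
    if np.isnan(values[off]).any():
        if not observed.any():
            raise ValidationError(
                "no observed off-diagonal similarities; cannot impute"
            )
        fill = values[observed].min()
        values[np.isnan(values)] = fill
    return pd.DataFrame(values, index=similarity.index, columns=similarity.columns)


def distance_of_similarity_profiles(similarity: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between rows of the cosine-similarity matrix.

    Two drugs are close when they relate to the whole drug panel in the same
    way.  ``similarity`` must be complete -- impute first.
    """
    if similarity.isna().to_numpy().any():
        raise ValidationError(
            "similarity matrix contains missing entries; run imputation first"
        )
    dist = squareform(pdist(similarity.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(dist, index=similarity.index, columns=similarity.index)


def ward_cophenetic(distance: pd.DataFrame) -> tuple[LinkageTree, pd.DataFrame]:
    """Ward linkage of a distance matrix and the resulting cophenetic matrix.

    The cophenetic distance of drugs i and j is the height of the merge at
    which they first join; the returned matrix is symmetric, zero-diagonal
    and ultrametric.  Merge ties are broken by the smallest cluster index,
    which makes the linkage deterministic.
    """
    n = len(distance)
    if n < 2:
        raise ValidationError(f"need at least 2 drugs to cluster, got {n}")
    condensed = squareform(distance.to_numpy(dtype=float), checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    tree = LinkageTree(linkage=linkage, ids=tuple(distance.index))
    coph = squareform(hierarchy.cophenet(linkage))
    coph_df = pd.DataFrame(coph, index=distance.index, columns=distance.columns)
    return tree, coph_df


def drug_drug_distance(
    monotherapy: MonotherapyMatrix,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    return_tree: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, LinkageTree]:
    """Full pipeline: monotherapy matrix -> cophenetic drug-drug distances.

    Deterministic composition of cosine similarity, imputation, row-profile
    Euclidean distance and Ward clustering.
    """
    similarity = impute_missing_similarity(
        cosine_similarity_matrix(monotherapy, min_overlap=min_overlap)
    )
    distance = distance_of_similarity_profiles(similarity)
    tree, coph = ward_cophenetic(distance)
    if return_tree:
        return coph, tree
    return coph
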
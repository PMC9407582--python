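"""Population-structure views of a RIP genotype panel: numeric genotype
matrices, PCA, and Euclidean hierarchical clustering for heatmap ordering.

Genotypes are coded by insertion-allele dose: -/- -> 0, +/- -> 1,
+/+ -> 2.  Missing entries stay missing in the stored matrix and are
imputed by the column mean only inside an analysis step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import GENOTYPE_DOSE

_DOSE_TO_SYMBOL = {v: k for k, v in GENOTYPE_DOSE.items()}


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # loci x components
    variance_explained: np.ndarray


@dataclass(frozen=True)
class ClusterResult:
    row_order: list
    merge_tree: np.ndarray  # scipy linkage matrix


def encode_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a genotype table into an individuals x loci dose matrix.

    Codes: "+/+" -> 2, "+/-" -> 1, "-/-" -> 0; missing genotypes stay NaN.
    """
    table = genotypes.copy()
    bad = set(table["genotype"].dropna()) - set(GENOTYPE_DOSE)
    if bad:
        raise ValueError(f"unknown genotype symbols {sorted(bad)!r}")
    table["dose"] = table["genotype"].map(GENOTYPE_DOSE)
    matrix = table.pivot(index="individual_id", columns="locus", values="dose")
    # keep first-appearance order of individuals, sorted loci
    order = table["individual_id"].drop_duplicates()
    return matrix.reindex(index=order, columns=sorted(matrix.columns)).astype(float)


def decode_matrix(matrix: pd.DataFrame, breed_of: dict | None = None) -> pd.DataFrame:
    """Inverse of :func:`encode_matrix` (missing stays missing)."""
    rows = []
    for individual, row in matrix.iterrows():
        for locus, dose in row.items():
            genotype = None if pd.isna(dose) else _DOSE_TO_SYMBOL[int(dose)]
            breed = breed_of.get(individual, "") if breed_of else ""
            rows.append((individual, breed, locus, genotype))
    return pd.DataFrame(rows, columns=["individual_id", "breed", "locus", "genotype"])


def _impute_column_means(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix.fillna(matrix.mean(axis=0))


def pca(matrix: pd.DataFrame, k: int = 2) -> PcaResult:
    """Principal component analysis of a genotype dose matrix.

    Columns are mean-centered (not scaled), constant columns dropped, and
    the SVD taken; scores are the row projections.  Sign convention: the
    largest-magnitude loading of each component is positive.
    variance_explained = squared singular values over total variance.
    """
    filled = _impute_column_means(matrix)
    filled = filled.loc[:, filled.std(axis=0, ddof=0) > 0]
    if filled.shape[0] < 2 or filled.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 non-constant columns for PCA")
    x = filled.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating")
        k = rank
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    var = s**2 / np.sum(s**2)
    comp = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=filled.index, columns=comp),
        loadings=pd.DataFrame(vt[:k].T, index=filled.columns, columns=comp),
        variance_explained=var[:k],
    )


def hierarchical_cluster(matrix: pd.DataFrame, linkage: str = "complete") -> ClusterResult:
    """Agglomerative clustering on Euclidean distances between rows.

    Missing entries are imputed by column means for the distance
    computation only.  Returns the leaf order (for heatmap rendering) and
    the scipy linkage matrix.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    filled = _impute_column_means(matrix)
    dists = pdist(filled.to_numpy(dtype=float), metric="euclidean")
    tree = hierarchy.linkage(dists, method=linkage)
    leaves = hierarchy.leaves_list(tree)
    return ClusterResult(row_order=[filled.index[i] for i in leaves], merge_tree=tree)


def cut_clusters(result: ClusterResult, n_clusters: int) -> dict:
    """Flat cluster labels at an n-cluster cut of the merge tree.

    fcluster labels follow original row order; row ids are recovered by
    inverting the leaf permutation.
    """
    labels = hierarchy.fcluster(result.merge_tree, t=n_clusters, criterion="maxclust")
    leaves = hierarchy.leaves_list(result.merge_tree)
    n = result.merge_tree.shape[0] + 1
    original = [None] * n
    for pos, leaf in enumerate(leaves):
        original[leaf] = result.row_order[pos]
    return dict(zip(original, labels))


def breed_pool_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Breed-level matrix: mean insertion dose per breed x locus.

    Emulates pooled-sample screening, where each breed contributes one row
    summarizing its allele content at each locus.
    """
    table = genotypes.dropna(subset=["genotype"]).copy()
    table["dose"] = table["genotype"].map(GENOTYPE_DOSE)
    return table.pivot_table(index="breed", columns="locus", values="dose", aggfunc="mean")
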
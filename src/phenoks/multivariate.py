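"""Multivariate analysis of compound Z profiles.

PCA of the compound × (descriptor, time) Z matrix, Ward hierarchical
clustering of the retained principal-component scores, dendrogram cutting
(largest merge-height gap or fixed k), and the auxiliary clustering of the
descriptor–descriptor correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PCAModel",
    "ClusteringResult",
    "pca_reduce",
    "ward_cluster",
    "cut_tree",
    "descriptor_correlation_clusters",
]

# Eigenvalues below this fraction of the largest are numerical zeros
# (a 15-sample matrix has at most 14 non-degenerate components).
_RANK_RTOL = 1e-10


@dataclass
class PCAModel:
    """Principal components of a centered (not rescaled) Z matrix.

    Z-score columns are already on a common standardized scale, so PCA is
    run on the covariance of the centered matrix; variance fractions are
    over the non-degenerate (numerically non-zero) components only.
    """

    loadings: pd.DataFrame         # columns x PCs
    scores: pd.DataFrame           # samples x PCs
    eigenvalues: np.ndarray        # non-zero eigenvalues, descending
    variance_fractions: np.ndarray
    n_components_retained: int
    var_threshold: float
    mean_: np.ndarray

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_components_retained]

    def reconstruct(self) -> pd.DataFrame:
        """Full-rank reconstruction of the centered input matrix."""
        recon = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(recon + self.mean_, index=self.scores.index,
                            columns=self.loadings.index)


@dataclass
class ClusteringResult:
    """Ward linkage tree over samples plus the flat cut.

    ``linkage`` is the scipy (n-1) x 4 merge table (Ward criterion on
    Euclidean distances; merge heights are non-decreasing). ``labels`` holds
    the flat cluster assignment from ``cut_rationale`` ("largest_gap" or
    "fixed_k=<k>").
    """

    linkage: np.ndarray
    sample_ids: list
    labels: pd.Series
    n_clusters: int
    cut_rationale: str


def pca_reduce(z_matrix: pd.DataFrame, var_threshold: float = 0.95) -> PCAModel:
    """PCA of the Z matrix; retain the fewest PCs reaching ``var_threshold``.

    Columns are mean-centered but not rescaled. Eigendecomposition is done
    through the SVD of the centered matrix; eigenvalues of the sample
    covariance are s^2/(n-1). With n samples in general position exactly
    n - 1 components are non-zero and their variance fractions sum to 1.
    """
    if len(z_matrix) < 2:
        raise ValueError("PCA requires at least 2 samples")
    if z_matrix.isna().any().any():
        raise ValueError("Z matrix contains missing values")
    x = z_matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    nonzero = s > (s[0] * _RANK_RTOL if s.size and s[0] > 0 else 0)
    u, s, vt = u[:, nonzero], s[nonzero], vt[nonzero]
    eig = s**2 / (len(x) - 1)
    frac = eig / eig.sum()
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    pcs = [f"PC{i + 1}" for i in range(s.size)]
    scores = pd.DataFrame(u * s, index=z_matrix.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=z_matrix.columns, columns=pcs)
    return PCAModel(loadings=loadings, scores=scores, eigenvalues=eig,
                    variance_fractions=frac, n_components_retained=k,
                    var_threshold=var_threshold, mean_=mean)


def ward_cluster(scores: pd.DataFrame, cut_mode: str = "largest_gap",
                 k: int | None = None) -> ClusteringResult:
    """Agglomerative Ward clustering (Euclidean base distance) of samples.

    Each merge joins the pair of clusters with the minimal increase in total
    within-cluster sum of squares. The full tree is returned along with the
    flat labels from :func:`cut_tree`.
    """
    ids = list(scores.index)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    if len(ids) < 2:
        raise ValueError("clustering requires at least 2 samples")
    link = hierarchy.linkage(scores.to_numpy(dtype=float), method="ward")
    result = ClusteringResult(linkage=link, sample_ids=ids,
                              labels=pd.Series(1, index=ids),
                              n_clusters=1, cut_rationale="")
    labels = cut_tree(result, mode=cut_mode, k=k)
    result.labels = labels
    result.n_clusters = int(labels.nunique())
    result.cut_rationale = cut_mode if cut_mode != "fixed_k" else f"fixed_k={k}"
    return result


def cut_tree(result: ClusteringResult, mode: str = "largest_gap",
             k: int | None = None) -> pd.Series:
    """Flatten a linkage tree into cluster labels.

    ``largest_gap`` cuts below the largest difference between successive
    merge heights; when every merge happens at the same height (e.g. all
    samples identical) there is no gap and a single cluster is returned.
    ``fixed_k`` is the standard k-cluster cut.
    """
    link = result.linkage
    n = len(result.sample_ids)
    if mode == "fixed_k":
        if k is None or not (1 <= k <= n):
            raise ValueError(f"k must be in 1..{n}")
        flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    elif mode == "largest_gap":
        heights = link[:, 2]
        gaps = np.diff(heights)
        if gaps.size == 0 or np.all(gaps <= 0):
            flat = np.ones(n, dtype=int)
        else:
            # cutting between merge i and i+1 leaves n - (i + 1) clusters;
            # ties go to the earliest gap (more clusters)
            i = int(np.argmax(gaps))
            flat = hierarchy.fcluster(link, t=n - i - 1, criterion="maxclust")
    else:
        raise ValueError(f"unknown cut mode: {mode!r}")
    return pd.Series(flat, index=result.sample_ids, name="cluster")


def descriptor_correlation_clusters(
    z_matrix: pd.DataFrame,
    major_k: int = 7,
    minor_k: int = 14,
):
    """Cluster descriptor columns by the correlation of their Z profiles.

    Pearson correlation r between every pair of (descriptor, time) columns
    is computed across compounds; columns are hierarchically clustered on
    the 1 - r distance (average linkage) and group labels are reported at
    two cut levels (major / minor). Zero-variance columns are excluded.

    Returns (correlation DataFrame, linkage, major labels, minor labels,
    excluded column list).
    """
    if len(z_matrix) < 3:
        raise ValueError("need >= 3 compounds for column correlations")
    var = z_matrix.var(axis=0)
    excluded = list(z_matrix.columns[var == 0])
    zm = z_matrix.loc[:, var > 0]
    corr = zm.corr()
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    m = len(corr)
    major = hierarchy.fcluster(link, t=min(major_k, m), criterion="maxclust")
    minor = hierarchy.fcluster(link, t=min(minor_k, m), criterion="maxclust")
    major_s = pd.Series(major, index=corr.index, name="major_group")
    minor_s = pd.Series(minor, index=corr.index, name="minor_group")
    return corr, link, major_s, minor_s, excluded
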
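"""Sample-level global structure: PCA, Pearson-distance clustering, ANOVA SS.

These are the sanity views computed before network construction: do samples
separate by cell type on the leading principal components, and how much of
the total (gene-standardized) variance lies between cell-type groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "PCAResult",
    "SampleDendrogram",
    "pca_samples",
    "variance_explained_by_celltype",
    "sample_distance",
    "hclust_samples",
]


@dataclass
class PCAResult:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame          # samples x components
    variance_fraction: np.ndarray # all min(n-1, p) fractions, sums to 1
    loadings: pd.DataFrame        # genes x components (unit-norm columns)


@dataclass
class SampleDendrogram:
    merges: list[tuple[int, int, float]]  # scipy-style (left, right, height)
    leaf_order: list[str]
    linkage_name: str
    labels: list[str]
    linkage_matrix: np.ndarray

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels for a cut into ``n_clusters`` groups."""
        lab = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return pd.Series(lab, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            left, right, h = self.merges[i - n]
            parts = []
            for c in (int(left), int(right)):
                parts.append(f"{node(c)}:{h - heights[c]:.6g}")
            heights[i] = h
            return "(" + ",".join(parts) + ")"

        for idx, (_, _, h) in enumerate(self.merges):
            heights[n + idx] = h
        return node(n + len(self.merges) - 1) + ";"


def pca_samples(expr: pd.DataFrame, n_components: int | None = None,
                scale: bool = False) -> PCAResult:
    """PCA of samples over genes via SVD of the centered sample x gene matrix.

    Each gene is centered (and optionally scaled to unit variance); variance
    fraction of component k is sigma_k^2 / sum(sigma^2). Component signs are
    fixed so the largest-magnitude score on each component is positive.
    """
    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = expr.T.to_numpy(dtype=float)  # samples x genes
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    scores = U * s
    # deterministic sign: largest-|score| entry positive (sample side, so
    # invariant to gene permutation)
    for k in range(scores.shape[1]):
        j = int(np.argmax(np.abs(scores[:, k])))
        if scores[j, k] < 0:
            scores[:, k] *= -1
            Vt[k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores[:, :n_components], index=expr.columns, columns=cols),
        variance_fraction=frac[:max_comp],
        loadings=pd.DataFrame(Vt[:n_components].T, index=expr.index, columns=cols),
    )


def variance_explained_by_celltype(expr: pd.DataFrame, metadata: pd.DataFrame) -> float:
    """Fraction of total gene-standardized variance explained by cell type.

    Per gene (standardized to mean 0, variance 1), a one-way ANOVA decomposes
    the sum of squares; the multivariate fraction is the ratio of summed
    between-group SS to summed total SS across all genes.
    """
    ct = metadata.loc[expr.columns, "cell_type"]
    groups = ct.unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 cell types")
    singletons = [g for g in groups if (ct == g).sum() < 2]
    if singletons:
        warnings.warn(
            f"cell types with a single sample contribute to SS: {singletons}",
            UserWarning,
        )
    X = expr.to_numpy(dtype=float)  # genes x samples
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    nonconst = sd[:, 0] > 0
    if not nonconst.all():
        warnings.warn("constant genes dropped from variance decomposition", UserWarning)
        X, mu, sd = X[nonconst], mu[nonconst], sd[nonconst]
    Z = (X - mu) / sd
    ss_total = (Z**2).sum()
    ss_between = 0.0
    for g in groups:
        mask = (ct == g).to_numpy()
        n_c = mask.sum()
        ss_between += n_c * (Z[:, mask].mean(axis=1) ** 2).sum()
    return float(ss_between / ss_total)


def sample_distance(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation distance between sample profiles: d = 1 - r."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = expr.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"sample {bad!r} has zero-variance expression profile")
    r = np.corrcoef(expr.T.to_numpy(dtype=float))
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def hclust_samples(distances: pd.DataFrame, linkage: str = "complete") -> SampleDendrogram:
    """Agglomerative clustering of samples from a precomputed distance matrix."""
    d = distances.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    from scipy.spatial.distance import squareform

    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    labels = list(distances.index)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return SampleDendrogram(
        merges=merges, leaf_order=order, linkage_name=linkage,
        labels=labels, linkage_matrix=Z,
    )
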
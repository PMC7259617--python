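"""Signed weighted co-expression network, module detection and eigengenes.

The network places an edge weight a_ij = ((1 + r_ij)/2)^beta between genes,
where r is the Pearson correlation across samples and beta a soft-threshold
power chosen by scanning scale-free topology fit against mean connectivity.
Pairwise similarity is then enriched with shared-neighbor structure through
the topological overlap measure

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

and genes are clustered by average linkage on the dissimilarity 1 - t. The
gene dendrogram is cut with a simplified dynamic cut (height quantile driven
by a deep-split level, with a minimum cluster size); close modules are merged
when their eigengenes are nearly collinear. Each module is summarized by its
eigengene — the first principal component of the module's standardized
expression — and associated with cell types through Pearson correlation
against one-vs-rest indicators with Student-t p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SoftThresholdScan",
    "ModuleAssignment",
    "ModuleEigengenes",
    "ModuleTraitCorrelation",
    "scale_free_fit_index",
    "soft_threshold_scan",
    "signed_adjacency",
    "tom_similarity",
    "cluster_genes",
    "merge_close_modules",
    "module_eigengene",
    "module_eigengenes",
    "module_trait_correlation",
    "detect_modules",
]

# deep-split level -> cut height as a fraction of the maximum merge height;
# larger levels cut lower, producing more and smaller clusters
DEEP_SPLIT_QUANTILE = {0: 0.95, 1: 0.97, 2: 0.99, 3: 0.995, 4: 0.999}


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # columns: beta, r_squared, mean_connectivity

    def pick(self, r2_cut: float = 0.8) -> int:
        """Smallest beta reaching the scale-free fit cut, else the best fit."""
        t = self.table
        ok = t[t["r_squared"] >= r2_cut]
        if len(ok):
            return int(ok["beta"].iloc[0])
        return int(t.loc[t["r_squared"].idxmax(), "beta"])


@dataclass
class ModuleAssignment:
    """Gene -> module label map; label 0 means unassigned."""

    labels: pd.Series
    min_cluster_size: int
    deep_split: int | None = None
    cut_height: float | None = None

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    @property
    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class ModuleEigengenes:
    eigengenes: pd.DataFrame           # modules x samples, unit variance
    loadings: dict[int, pd.Series]     # per-module unit-norm PC1 gene loadings
    variance_fraction: pd.Series       # per-module PC1 variance fraction


@dataclass
class ModuleTraitCorrelation:
    r: pd.DataFrame      # modules x cell types
    p: pd.DataFrame
    p_adj: pd.DataFrame  # Benjamini-Hochberg over the whole matrix
    n_samples: int

    def strongest_positive(self, module: int) -> str:
        """Cell type with the largest positive correlation for a module."""
        row = self.r.loc[module]
        return str(row.idxmax())


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; the fraction
    of genes per bin is regressed (log10) on the bin-mean connectivity
    (log10). The R^2 is signed by -sign(slope) so that only a decreasing
    distribution counts as scale-free.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def soft_threshold_scan(expr: pd.DataFrame, betas=None) -> SoftThresholdScan:
    """Scale-free fit index and mean connectivity across candidate powers."""
    if betas is None:
        betas = range(1, 21)
    betas = [int(b) for b in betas]
    if any(b < 1 for b in betas):
        raise ValueError("betas must be positive integers")
    if expr.shape[0] < 30:
        warnings.warn("fewer than 30 genes: scale-free fit is unreliable", UserWarning)
    r = np.corrcoef(expr.to_numpy(dtype=float))
    base = (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)  # exclude self-connectivity
    rows = []
    for b in betas:
        k = (base**b).sum(axis=1)
        rows.append(
            {"beta": b, "r_squared": scale_free_fit_index(k),
             "mean_connectivity": float(k.mean())}
        )
    return SoftThresholdScan(table=pd.DataFrame(rows))


def signed_adjacency(expr: pd.DataFrame, beta: int = 12) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + r_ij)/2)^beta, diagonal 1."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"gene {bad!r} has zero variance")
    r = np.corrcoef(X)
    a = ((1.0 + np.clip(r, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of a signed adjacency matrix."""
    A = adjacency.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if (A < 0).any() or (A > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    # with unit diagonal, (A @ A)_ij counts u = i and u = j, each adding a_ij
    L = A @ A - 2.0 * A
    k = A.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (L + A) / denom
    t[~np.isfinite(t)] = 0.0
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Contiguous labels 1..M sorted by decreasing module size; 0 kept."""
    sizes = labels[labels != 0].value_counts()
    order = sizes.sort_values(ascending=False).index
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    return labels.map(mapping).astype(int)


def cluster_genes(
    tom: pd.DataFrame,
    min_cluster_size: int = 20,
    deep_split: int = 2,
    quantile_map: dict[int, float] | None = None,
    core_ratio: float = 0.5,
) -> ModuleAssignment:
    """Cut the average-linkage gene tree on 1 - TOM into modules.

    A simplified dynamic cut in three steps. (1) The tree is cut at a fixed
    fraction of the maximum merge height (the fraction set by ``deep_split``;
    higher levels cut lower and split more finely). (2) Each cluster is
    reduced to its core: a gene is kept only if its mean TOM similarity to
    the rest of the cluster is at least ``core_ratio`` times the cluster's
    median such similarity — peripheral genes that attach to a tight cluster
    through a handful of weak edges (whose topological overlap is inflated by
    the min-connectivity denominator) are unassigned. (3) Clusters below
    ``min_cluster_size`` are labeled 0. Surviving modules are relabeled 1..M
    by decreasing size.
    """
    n = tom.shape[0]
    if min_cluster_size > n:
        raise ValueError("min_cluster_size exceeds the number of genes")
    qmap = DEEP_SPLIT_QUANTILE if quantile_map is None else quantile_map
    if deep_split not in qmap:
        raise ValueError(f"deep_split must be one of {sorted(qmap)}")
    T = tom.to_numpy(dtype=float)
    dissim = 1.0 - T
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    cut_height = qmap[deep_split] * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index, dtype=int)
    if 0 < core_ratio:
        for cl in labels.unique():
            members = np.flatnonzero((labels == cl).to_numpy())
            # iterate to a fixed point: dropping periphery tightens the core
            while members.size >= 3:
                sub = T[np.ix_(members, members)]
                mean_sim = (sub.sum(axis=1) - 1.0) / (members.size - 1)
                cut = core_ratio * np.median(mean_sim)
                drop = mean_sim < cut
                if not drop.any():
                    break
                labels.iloc[members[drop]] = 0
                members = members[~drop]
    sizes = labels[labels != 0].value_counts()
    small = sizes.index[sizes < min_cluster_size]
    labels[labels.isin(small)] = 0
    labels = _relabel_by_size(labels)
    return ModuleAssignment(
        labels=labels, min_cluster_size=min_cluster_size,
        deep_split=deep_split, cut_height=float(cut_height),
    )


def module_eigengene(expr: pd.DataFrame, module_genes) -> tuple[pd.Series, pd.Series, float]:
    """Eigengene (PC1 scores), unit-norm gene loadings and variance fraction.

    The module's genes are standardized per gene (mean 0, sd 1) over samples;
    PC1 of the resulting samples x genes matrix is the eigengene, rescaled to
    unit variance and sign-flipped so it correlates positively with the
    module's mean standardized expression.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    X = expr.loc[module_genes].to_numpy(dtype=float)  # genes x samples
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance gene in module")
    Z = ((X - mu) / sd).T  # samples x genes
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    eig = U[:, 0]
    load = Vt[0]
    mean_profile = Z.mean(axis=1)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig, load = -eig, -load
    eig = eig / eig.std(ddof=1)
    var = s**2
    frac = float(var[0] / var.sum())
    return (
        pd.Series(eig, index=expr.columns, name="eigengene"),
        pd.Series(load, index=module_genes, name="loading"),
        frac,
    )


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> ModuleEigengenes:
    """Eigengenes for every module in an assignment."""
    eigs, loads, fracs = {}, {}, {}
    for m in assignment.module_ids:
        e, l, f = module_eigengene(expr, assignment.genes_in(m))
        eigs[m], loads[m], fracs[m] = e, l, f
    return ModuleEigengenes(
        eigengenes=pd.DataFrame(eigs).T,
        loadings=loads,
        variance_fraction=pd.Series(fracs, dtype=float),
    )


def merge_close_modules(
    expr: pd.DataFrame, assignment: ModuleAssignment, cut_height: float = 0.05
) -> ModuleAssignment:
    """Iteratively merge module pairs whose eigengene dissimilarity < cut_height.

    Dissimilarity is 1 - cor(E_a, E_b); after each merge, eigengenes are
    recomputed and the search repeats until no pair is close enough. The
    module count never increases, and rerunning at the same cut height is a
    no-op.
    """
    if not 0 <= cut_height < 1:
        raise ValueError("cut_height must be in [0, 1)")
    labels = assignment.labels.copy()
    while True:
        mods = sorted(int(m) for m in labels.unique() if m != 0)
        if len(mods) < 2:
            break
        eigs = pd.DataFrame(
            {m: module_eigengene(expr, labels.index[labels == m])[0] for m in mods}
        )
        diss = 1.0 - eigs.corr().to_numpy()
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= cut_height:
            break
        keep, drop = mods[i], mods[j]
        labels[labels == drop] = keep
    labels = _relabel_by_size(labels)
    return ModuleAssignment(
        labels=labels, min_cluster_size=assignment.min_cluster_size,
        deep_split=assignment.deep_split, cut_height=assignment.cut_height,
    )


def module_trait_correlation(
    eigengenes: pd.DataFrame, metadata: pd.DataFrame
) -> ModuleTraitCorrelation:
    """Pearson correlation of eigengenes with one-vs-rest cell-type indicators.

    p-values come from the Student-t transform t = r sqrt(n-2)/sqrt(1-r^2)
    on n - 2 degrees of freedom (two-sided); |r| = 1 yields p = 0. BH-adjusted
    p-values over the whole module x cell-type matrix are reported alongside.
    """
    samples = eigengenes.columns
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples")
    ct = metadata.loc[samples, "cell_type"]
    indicators = pd.get_dummies(ct).astype(float)  # samples x cell types
    E = eigengenes.to_numpy(dtype=float)
    I = indicators.to_numpy(dtype=float)
    Ez = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, ddof=0, keepdims=True)
    Iz = (I - I.mean(axis=0, keepdims=True)) / I.std(axis=0, ddof=0, keepdims=True)
    r = np.clip(Ez @ Iz / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[r == 0] = 1.0
    p_adj = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    idx, cols = eigengenes.index, indicators.columns
    return ModuleTraitCorrelation(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=cols),
        n_samples=n,
    )


def detect_modules(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    beta: int = 12,
    min_cluster_size: int = 20,
    deep_split: int = 2,
    merge_cut_height: float = 0.05,
) -> tuple[ModuleAssignment, ModuleEigengenes, ModuleTraitCorrelation]:
    """Full module-detection stage: adjacency -> TOM -> cut -> merge -> traits."""
    adj = signed_adjacency(expr, beta=beta)
    tom = tom_similarity(adj)
    assignment = cluster_genes(tom, min_cluster_size=min_cluster_size,
                               deep_split=deep_split)
    if assignment.module_ids:
        assignment = merge_close_modules(expr, assignment, cut_height=merge_cut_height)
    eigs = module_eigengenes(expr, assignment)
    traits = (
        module_trait_correlation(eigs.eigengenes, metadata)
        if assignment.module_ids
        else ModuleTraitCorrelation(
            r=pd.DataFrame(), p=pd.DataFrame(), p_adj=pd.DataFrame(),
            n_samples=expr.shape[1],
        )
    )
    return assignment, eigs, traits
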
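"""Top Expressing Genes, Module Representative Genes and term enrichment.

Two targeted gene lists summarize a module: TEGs are module genes whose mean
expression in the module's associated cell types reaches the 98th percentile
of the whole gene universe; MRGs are the genes whose squared PC1 loadings
accumulate 20% of the module eigengene's first component. Generic gene-set
enrichment is a hypergeometric upper tail over a GMT annotation, reported
when the fold enrichment is at least two and p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "associated_celltypes",
    "top_expressing_genes",
    "module_representative_genes",
    "term_enrichment",
]


def read_gmt(path) -> dict[str, dict]:
    """Parse a GMT file into {term_id: {"description": ..., "genes": set}}."""
    terms: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: need term, description, >=1 gene")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"GMT line {lineno}: term {term!r} has no genes")
            terms[term] = {"description": desc, "genes": set(genes)}
    return terms


def associated_celltypes(traits, module: int, max_p: float = 0.05) -> list[str]:
    """Cell types positively associated with a module (r > 0 and p < max_p)."""
    r, p = traits.r.loc[module], traits.p.loc[module]
    return list(r.index[(r > 0) & (p < max_p)])


def top_expressing_genes(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    module_genes,
    celltypes,
    percentile: float = 98.0,
) -> list[str]:
    """Module genes at or above the universe-wide expression percentile.

    Mean expression is taken over all samples of the associated cell types
    (pooled when a module is associated with several); the threshold is the
    ``percentile`` of these means over the whole gene universe in ``expr``.
    Returned sorted by decreasing mean.
    """
    celltypes = list(celltypes)
    if not celltypes:
        raise ValueError("associated cell-type set is empty")
    samples = metadata.index[metadata["cell_type"].isin(celltypes)]
    samples = [s for s in samples if s in expr.columns]
    if not samples:
        raise ValueError(f"no samples of cell types {celltypes}")
    means = expr[samples].mean(axis=1)
    threshold = np.percentile(means.to_numpy(), percentile)
    mg = [g for g in module_genes if g in means.index]
    hits = means.loc[mg]
    hits = hits[hits >= threshold]
    return list(hits.sort_values(ascending=False).index)


def module_representative_genes(
    pc1_loadings: pd.Series,
    pc_fraction: float = 0.20,
    max_genes: int | None = None,
) -> list[str]:
    """Shortest loading-ranked prefix accumulating ``pc_fraction`` of PC1.

    Gene contribution is the squared unit-norm loading; genes are ranked by
    decreasing contribution (ties broken by gene id) and the prefix whose
    cumulative contribution first reaches ``pc_fraction`` is returned,
    truncated to ``max_genes`` when a cap is given.
    """
    if len(pc1_loadings) == 0:
        raise ValueError("empty loadings")
    total = float((pc1_loadings**2).sum())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("loadings must be unit-norm")
    contrib = (pc1_loadings**2).rename("contribution")
    ordered = contrib.reset_index()
    ordered.columns = ["gene", "contribution"]
    ordered = ordered.sort_values(
        ["contribution", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    cum = ordered["contribution"].cumsum()
    n_needed = int(np.searchsorted(cum.to_numpy(), pc_fraction - 1e-12) + 1)
    n_needed = min(n_needed, len(ordered))
    genes = list(ordered["gene"].iloc[:n_needed])
    if max_genes is not None and len(genes) > max_genes:
        genes = genes[:max_genes]
    return genes


def term_enrichment(
    module_genes,
    universe,
    annotation: dict[str, dict],
    min_fold: float = 2.0,
    max_p: float = 0.05,
    filtered: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a module.

    For each term: population N = |universe|, successes K = |term ∩ universe|,
    draws n = |module|, observed k = |term ∩ module|; p = P(X >= k) and
    fold = (k/n)/(K/N). With ``filtered`` (default), rows are kept when
    fold >= min_fold and p < max_p; otherwise the full table is returned.
    A BH-adjusted column is computed over all tested terms before filtering.
    """
    universe = set(universe)
    module = set(module_genes)
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    N, n = len(universe), len(module)
    rows = []
    for term, rec in annotation.items():
        term_genes = rec["genes"] & universe
        K = len(term_genes)
        if K == 0:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped",
                          UserWarning)
            continue
        k = len(term_genes & module)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append(
            {"term": term, "description": rec.get("description", ""),
             "k": k, "n": n, "K": K, "N": N, "fold": fold, "p": p}
        )
    table = pd.DataFrame(
        rows, columns=["term", "description", "k", "n", "K", "N", "fold", "p"]
    )
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        if filtered:
            table = table[(table["fold"] >= min_fold) & (table["p"] < max_p)]
        table = table.sort_values("p").reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table
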
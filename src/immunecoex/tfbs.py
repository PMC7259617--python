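"""Strand-aware promoter windows, ChIP-seq peak overlap and TFBS enrichment.

Promoters are defined as -1000 to +500 bases around each gene's TSS on the
gene's strand (1-based inclusive, emitted as 0-based half-open BED-style
intervals). A gene x TF presence matrix records whether any peak of a TF
overlaps the promoter by at least one base; per-TF over-representation in a
module's promoters is a hypergeometric upper tail against the universe of
genes with a promoter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_tss",
    "read_peaks_bed",
    "define_promoters",
    "map_peaks_to_promoters",
    "tfbs_enrichment",
]


def read_tss(path, multiple: str = "most_upstream") -> pd.DataFrame:
    """Read a TSS table (gene, chrom, strand, tss; 1-based coordinates).

    With several TSS per gene, ``most_upstream`` keeps the most upstream on
    the gene's strand (smallest coordinate on +, largest on -); ``all`` keeps
    every record (union-of-promoters semantics downstream).
    """
    tss = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "strand", "tss"}
    if not required.issubset(tss.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    bad = ~tss["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbol {tss.loc[bad, 'strand'].iloc[0]!r}")
    if (tss["tss"] < 1).any():
        raise ValueError("TSS coordinates must be >= 1 (1-based)")
    if multiple == "most_upstream":
        plus = tss[tss["strand"] == "+"].sort_values("tss").drop_duplicates("gene")
        minus = (
            tss[tss["strand"] == "-"]
            .sort_values("tss", ascending=False)
            .drop_duplicates("gene")
        )
        tss = pd.concat([plus, minus]).drop_duplicates("gene")
    elif multiple != "all":
        raise ValueError("multiple must be 'most_upstream' or 'all'")
    return tss.reset_index(drop=True)


def read_peaks_bed(path) -> pd.DataFrame:
    """Read BED3+name peaks (chrom, start, end, TF name; 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line {lineno}: need chrom, start, end, name")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"BED line {lineno}: start must be < end")
            rows.append({"tf": name, "chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows, columns=["tf", "chrom", "start", "end"])


def define_promoters(
    tss: pd.DataFrame, upstream: int = 1000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter intervals around each TSS.

    On the + strand the window is [TSS - upstream, TSS + downstream] in
    1-based inclusive coordinates; on the - strand it is mirrored,
    [TSS - downstream, TSS + upstream]. Intervals are emitted as 0-based
    half-open [start, end) and clipped at the chromosome origin.
    """
    bad = ~tss["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbol {tss.loc[bad, 'strand'].iloc[0]!r}")
    t = tss["tss"].to_numpy(dtype=np.int64)
    plus = (tss["strand"] == "+").to_numpy()
    lo = np.where(plus, t - upstream, t - downstream)
    hi = np.where(plus, t + downstream, t + upstream)
    start = np.maximum(lo - 1, 0)
    end = hi  # 1-based inclusive hi -> half-open end
    return pd.DataFrame(
        {"gene": tss["gene"], "chrom": tss["chrom"], "start": start,
         "end": end, "strand": tss["strand"]}
    )


def map_peaks_to_promoters(
    peaks: pd.DataFrame, promoters: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Gene x TF binary presence of peak-promoter overlap (half-open semantics).

    presence(g, t) = 1 iff some peak of TF t overlaps gene g's promoter by at
    least ``min_overlap`` bases. Chromosome naming schemes are validated:
    peaks on chromosomes absent from the promoter set trigger a warning with
    counts.
    """
    prom_chroms = set(promoters["chrom"])
    peak_chroms = set(peaks["chrom"])
    unmatched = peak_chroms - prom_chroms
    if unmatched and peak_chroms:
        n_off = int(peaks["chrom"].isin(unmatched).sum())
        warnings.warn(
            f"{n_off}/{len(peaks)} peaks on chromosomes absent from promoters "
            f"({sorted(unmatched)[:5]}...)",
            UserWarning,
        )
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in promoters.groupby("chrom"):
        tree = IntervalTree()
        for row in grp.itertuples():
            tree[row.start:row.end] = row.gene
        trees[chrom] = tree
    genes = list(pd.unique(promoters["gene"]))
    tfs = sorted(pd.unique(peaks["tf"]))
    presence = pd.DataFrame(0, index=genes, columns=tfs, dtype=np.int8)
    tf_col = {tf: i for i, tf in enumerate(tfs)}
    arr = presence.to_numpy()
    gene_row = {g: i for i, g in enumerate(genes)}
    for row in peaks.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            if min(iv.end, row.end) - max(iv.begin, row.start) >= min_overlap:
                arr[gene_row[iv.data], tf_col[row.tf]] = 1
    return presence


def tfbs_enrichment(
    module_genes, presence: pd.DataFrame, max_p: float = 0.05,
    filtered: bool = True,
) -> pd.DataFrame:
    """Per-TF hypergeometric enrichment of promoter binding in a module.

    Universe N = genes with a promoter (presence rows); K = genes bound by
    the TF; n = module size; k = bound module genes. p = P(X >= k),
    fold = (k/n)/(K/N). Filtered at p < ``max_p`` by default; the unfiltered
    table (``filtered=False``) carries every TF with K > 0 plus a BH column.
    """
    universe = set(presence.index)
    module = set(module_genes)
    if not module <= universe:
        missing = sorted(module - universe)[0]
        raise ValueError(f"module gene {missing!r} not in the promoter universe")
    N, n = len(universe), len(module)
    mod_idx = presence.index.isin(module)
    rows = []
    for tf in presence.columns:
        col = presence[tf].to_numpy()
        K = int(col.sum())
        if K == 0:
            warnings.warn(f"TF {tf!r} binds no promoter in the universe; skipped",
                          UserWarning)
            continue
        k = int(col[mod_idx].sum())
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append({"tf": tf, "k": k, "n": n, "K": K, "N": N, "fold": fold, "p": p})
    table = pd.DataFrame(rows, columns=["tf", "k", "n", "K", "N", "fold", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        if filtered:
            table = table[table["p"] < max_p]
        table = table.sort_values("p").reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table
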
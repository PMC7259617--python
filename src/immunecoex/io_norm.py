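"""Count-matrix input, low-expression filtering, TMM normalization and log2-CPM.

The pipeline starts from a gene x sample matrix of raw read counts plus a
sample metadata table (cell type, individual). Between-sample normalization
uses the trimmed mean of M-values (TMM): per-gene log2 ratios against a
reference sample are trimmed in both the ratio (M) and abundance (A)
dimensions and averaged with inverse-variance weights; the resulting scale
factors are rescaled to geometric mean 1. Expression values are
variance-stabilized as log2 counts per million with a prior count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "read_counts",
    "filter_low_expressed",
    "tmm_factors",
    "normalize_log_cpm",
    "cpm",
]


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with aligned sample metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integers; index = gene ids, columns = sample ids.
    metadata : pandas.DataFrame
        Indexed by sample id, with columns ``cell_type`` and ``individual``,
        one row per count column, in count-column order.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("count matrix needs at least 2 genes and 2 samples")
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        missing = [s for s in c.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(
                f"sample {missing[0]!r} present in counts but absent from metadata"
            )
        self.counts = c.astype(np.int64)
        self.metadata = self.metadata.loc[c.columns]
        self.metadata.index.name = "sample"

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample library size L_j (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors f_j with effective library sizes L_j * f_j."""

    factors: pd.Series
    library_sizes: pd.Series
    ref_sample: str
    trim_m: float = 0.30
    trim_a: float = 0.05

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


def _read_mtx(count_path: Path) -> pd.DataFrame:
    from scipy.io import mmread

    mat = mmread(count_path)
    genes_path = count_path.with_suffix(".genes")
    samples_path = count_path.with_suffix(".samples")
    for p in (genes_path, samples_path):
        if not p.exists():
            raise FileNotFoundError(f"MatrixMarket sidecar missing: {p}")
    genes = genes_path.read_text().split()
    samples = samples_path.read_text().split()
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if dense.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    return pd.DataFrame(dense, index=genes, columns=samples)


def read_counts(count_path, metadata_path) -> CountMatrix:
    """Read a count matrix (TSV or MatrixMarket) and its sample metadata TSV.

    TSV counts have a header row of sample ids and gene ids in the first
    column. MatrixMarket input (``.mtx``) expects ``.genes`` / ``.samples``
    sidecar files listing row and column identifiers. The metadata TSV must
    have columns ``sample``, ``cell_type``, ``individual``.
    """
    count_path = Path(count_path)
    if count_path.suffix == ".mtx":
        counts = _read_mtx(count_path)
    else:
        counts = pd.read_csv(count_path, sep="\t", index_col=0)
    counts.index.name = None
    counts.columns.name = None
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample", "cell_type", "individual"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample identifier in metadata: {dup!r}")
    meta = meta.set_index("sample")
    return CountMatrix(counts=counts, metadata=meta)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample: counts_gj / L_j * 1e6."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    return counts / lib * 1e6


def filter_low_expressed(
    cm: CountMatrix, cpm_threshold: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Keep genes with CPM >= ``cpm_threshold`` in at least ``min_samples`` samples.

    ``min_samples`` defaults to the smallest cell-type group size, so a gene
    expressed in only one cell type survives. Library sizes are those of the
    unfiltered matrix; gene order is preserved.
    """
    if cpm_threshold <= 0:
        raise ValueError("cpm_threshold must be positive")
    if min_samples is None:
        min_samples = int(cm.metadata["cell_type"].value_counts().min())
    n = cm.counts.shape[1]
    if not 1 <= min_samples <= n:
        raise ValueError(f"min_samples must be in [1, {n}]")
    keep = (cpm(cm.counts) >= cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"all genes removed at cpm_threshold={cpm_threshold}, "
            f"min_samples={min_samples}"
        )
    return CountMatrix(counts=cm.counts.loc[keep], metadata=cm.metadata)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Robinson-Oshlack trimmed weighted mean of M-values for one sample pair.

    Genes with a zero count in either sample are excluded pairwise. Trims
    ``trim_m`` of the ranked M-values and ``trim_a`` of the ranked A-values
    from each tail, then averages the surviving M-values with
    inverse-asymptotic-variance (delta-method binomial) weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        raise ValueError("sample shares no nonzero genes with the reference")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def choose_reference_sample(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile CPM is closest to the mean upper-quartile."""
    uq = cpm(counts).quantile(0.75, axis=0)
    return str((uq - uq.mean()).abs().idxmin())


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose 75th-percentile CPM is closest
    to the mean 75th percentile across samples.
    """
    counts = cm.counts
    lib = counts.sum(axis=0).astype(float)
    if ref_sample is None:
        ref_sample = choose_reference_sample(counts)
    elif ref_sample not in counts.columns:
        raise KeyError(f"unknown reference sample {ref_sample!r}")
    ref = counts[ref_sample].to_numpy(dtype=float)
    lib_ref = float(lib[ref_sample])
    raw = {}
    for s in counts.columns:
        try:
            raw[s] = _tmm_pair(
                counts[s].to_numpy(dtype=float), ref, float(lib[s]), lib_ref,
                trim_m, trim_a,
            )
        except ValueError as exc:
            raise ValueError(f"sample {s!r}: {exc}") from exc
    f = pd.Series(raw, dtype=float).loc[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    return NormalizationFactors(
        factors=f, library_sizes=lib, ref_sample=ref_sample,
        trim_m=trim_m, trim_a=trim_a,
    )


def normalize_log_cpm(
    cm: CountMatrix,
    factors: NormalizationFactors | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2-CPM with effective (TMM-scaled) library sizes.

    value = log2( (count + prior_count) / (L_j * f_j + 1) * 1e6 )

    Returns a genes x samples DataFrame; normalization provenance is stored
    in ``DataFrame.attrs``.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if factors is None:
        factors = tmm_factors(cm)
    eff = factors.effective_library_sizes.loc[cm.counts.columns]
    if (eff <= 0).any():
        bad = eff.index[eff <= 0][0]
        raise ValueError(f"non-positive effective library size for sample {bad!r}")
    expr = np.log2((cm.counts + prior_count) / (eff + 1.0) * 1e6)
    expr.attrs["prior_count"] = prior_count
    expr.attrs["ref_sample"] = factors.ref_sample
    expr.attrs["normalization"] = "TMM log2-CPM"
    return expr
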
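"""Synthetic study generator: sorted immune-cell counts with planted structure.

Emulates the statistical shape of a sorted-population bulk RNA-seq study:
nine immune cell types (five lymphoid, four myeloid) sampled from twelve
individuals, negative-binomial counts with log-normal library-size variation,
genes organized into cell-type-specific co-expression modules, planted
fate-specific transcription factors on a hematopoietic differentiation tree,
and annotation fixtures (TSS table, ChIP-seq-like peak BED, GMT terms) with
planted promoter-TFBS and term enrichments.

The count model is, on the natural-log scale,

    mu_gj = b_g + delta_{g, c(j)} + lambda_g * f_{m(g), j}

with b_g a gene baseline, delta the cell-type effect (positive in a module's
associated cell type, negative elsewhere so the module is silent), and f a
per-sample latent factor shared by a module's genes (unit variance in "on"
samples, zero otherwise). Counts are NB(mean = s_j * exp(mu_gj), dispersion
phi_g) with s_j a log-normal library factor. Ground truth records gene-module
membership, module-cell-type association, the per-sample module activity
(delta pattern plus factor), planted fate TFs and annotation plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_norm import CountMatrix
from .tf_fate import read_tree

__all__ = [
    "ModuleSpec",
    "FateTFSpec",
    "TFBSPlant",
    "TermPlant",
    "SimulationConfig",
    "GroundTruth",
    "default_tree_dict",
    "simulate_counts",
    "simulate_annotation",
    "write_fixtures",
]

CELL_TYPES = [
    "B", "CD4T", "CD8T", "GDT", "NK",            # lymphoid
    "Neutrophil", "Monocyte", "Macrophage", "MacrophageLPS",  # myeloid
]

LYMPHOID = ["B", "CD4T", "CD8T", "GDT", "NK"]
MYELOID = ["Neutrophil", "Monocyte", "Macrophage", "MacrophageLPS"]


def default_tree_dict() -> dict:
    """Hematopoietic differentiation tree over the nine cell types."""
    return {
        "name": "HSC",
        "children": [
            {
                "name": "Lymphoid",
                "children": [
                    {"name": "B"},
                    {
                        "name": "TNK",
                        "children": [
                            {"name": "NK"},
                            {
                                "name": "T",
                                "children": [
                                    {"name": "CD4T"},
                                    {"name": "CD8T"},
                                    {"name": "GDT"},
                                ],
                            },
                        ],
                    },
                ],
            },
            {
                "name": "Myeloid",
                "children": [
                    {"name": "Neutrophil"},
                    {
                        "name": "MonoMac",
                        "children": [
                            {"name": "Monocyte"},
                            {
                                "name": "Mac",
                                "children": [
                                    {"name": "Macrophage"},
                                    {"name": "MacrophageLPS"},
                                ],
                            },
                        ],
                    },
                ],
            },
        ],
    }


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    celltypes: tuple[str, ...]     # associated ("on") cell types
    on_shift: float = 2.5          # delta for on cell types (natural log)
    off_shift: float = -2.0        # delta elsewhere (module silent)
    loading_scale: tuple[float, float] = (0.25, 0.45)  # lambda_g ~ U(a, b)


@dataclass(frozen=True)
class FateTFSpec:
    """A TF planted to be fate-specific at one decision of the tree."""

    name: str
    fate_celltypes: tuple[str, ...]
    decision_id: str
    fate_mean: float = 2500.0
    contrast_mean: float = 10.0


@dataclass(frozen=True)
class TFBSPlant:
    tf: str
    module: int                    # 1-based planted-module index
    foreground: float = 0.8        # P(peak in promoter | module gene)
    background: float = 0.1


@dataclass(frozen=True)
class TermPlant:
    term: str
    module: int
    foreground: float = 0.6        # P(gene in term | module gene)
    background: float = 0.1


def _default_modules() -> tuple[ModuleSpec, ...]:
    return (
        ModuleSpec(size=40, celltypes=("B",)),
        ModuleSpec(size=80, celltypes=("NK",)),
        ModuleSpec(size=120, celltypes=("Neutrophil",)),
        ModuleSpec(size=160, celltypes=("Monocyte",)),
        ModuleSpec(size=200, celltypes=("CD4T",)),
    )


def _default_fate_tfs() -> tuple[FateTFSpec, ...]:
    return (
        FateTFSpec("TFFATE_LYMPHOID", tuple(LYMPHOID), "HSC:Lymphoid"),
        FateTFSpec("TFFATE_MYELOID", tuple(MYELOID), "HSC:Myeloid"),
        FateTFSpec("TFFATE_B", ("B",), "Lymphoid:B"),
        FateTFSpec("TFFATE_NK", ("NK",), "TNK:NK"),
        FateTFSpec("TFFATE_NEUT", ("Neutrophil",), "Myeloid:Neutrophil"),
        FateTFSpec("TFFATE_MAC", ("Macrophage", "MacrophageLPS"), "MonoMac:Mac"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000            # includes module genes, excludes planted TFs
    celltypes: tuple[str, ...] = tuple(CELL_TYPES)
    n_individuals: int = 12
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    baseline_log_mean: float = np.log(150.0)
    baseline_log_sd: float = 1.2
    module_base_log_mean: float = np.log(30.0)
    module_base_log_sd: float = 0.5
    dispersion: float = 0.08       # median NB dispersion phi
    dispersion_log_sd: float = 0.4
    library_log_sd: float = 0.3
    fate_tfs: tuple[FateTFSpec, ...] = field(default_factory=_default_fate_tfs)
    n_null_tfs: int = 10           # uniformly expressed TFs (never candidates)
    null_tf_mean: float = 300.0
    tfbs_plants: tuple[TFBSPlant, ...] = (TFBSPlant("TF_PLANT", 1),)
    n_background_tfbs: int = 4     # unenriched TFs in the peak file
    background_tfbs_rate: float = 0.15
    term_plants: tuple[TermPlant, ...] = (TermPlant("TERM_PLANT", 1),)
    n_background_terms: int = 5
    background_term_rate: float = 0.1
    gene_spacing: int = 10_000     # keeps promoter windows clear of the origin
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_individuals < 2:
            raise ValueError("need at least 2 genes and 2 individuals")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        unknown = [c for m in self.modules for c in m.celltypes
                   if c not in self.celltypes]
        if unknown:
            raise ValueError(f"unknown module cell type {unknown[0]!r}")
        for p in self.tfbs_plants + self.term_plants:
            if not 0 <= p.foreground <= 1 or not 0 <= p.background <= 1:
                raise ValueError("plant probabilities must lie in [0, 1]")
            if not 1 <= p.module <= len(self.modules):
                raise ValueError(f"plant references unknown module {p.module}")


@dataclass
class GroundTruth:
    module_labels: pd.Series                 # gene -> planted module (0 = none)
    module_celltypes: dict[int, tuple[str, ...]]
    module_activity: pd.DataFrame            # planted module x sample activity
    fate_tfs: dict[str, list[str]]           # decision id -> planted TF genes
    tf_list: list[str]                       # all genes flagged as TFs
    tfbs_plants: list[TFBSPlant]
    term_plants: list[TermPlant]
    tree: dict


def simulate_counts(config: SimulationConfig | None = None):
    """Generate counts, metadata and ground truth for one simulated study.

    Returns ``(CountMatrix, GroundTruth)``; deterministic for a fixed
    ``config.seed``.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    celltypes = list(config.celltypes)
    individuals = [f"I{i + 1:02d}" for i in range(config.n_individuals)]
    samples = [f"{ct}_{ind}" for ct in celltypes for ind in individuals]
    sample_ct = np.repeat(celltypes, config.n_individuals)
    n_samples = len(samples)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    module_labels = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m_idx, spec in enumerate(config.modules, start=1):
        module_labels[pos:pos + spec.size] = m_idx
        pos += spec.size

    # gene baselines: module genes sit lower so the on-state dominates
    b = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    is_module = module_labels > 0
    b[is_module] = rng.normal(
        config.module_base_log_mean, config.module_base_log_sd, is_module.sum()
    )

    mu = np.tile(b[:, None], (1, n_samples))
    activity = {}
    for m_idx, spec in enumerate(config.modules, start=1):
        rows = module_labels == m_idx
        on = np.isin(sample_ct, spec.celltypes)
        f = np.where(on, rng.normal(0.0, 1.0, n_samples), 0.0)
        lam = rng.uniform(*spec.loading_scale, rows.sum())
        delta = np.where(on, spec.on_shift, spec.off_shift)
        mu[rows] += delta[None, :] + lam[:, None] * f[None, :]
        activity[m_idx] = delta + f

    # planted TF genes appended after the co-expression gene universe
    tf_genes: list[str] = []
    tf_mu_rows: list[np.ndarray] = []
    fate_map: dict[str, list[str]] = {}
    for spec in config.fate_tfs:
        on = np.isin(sample_ct, spec.fate_celltypes)
        row = np.where(on, np.log(spec.fate_mean), np.log(max(spec.contrast_mean, 1e-6)))
        tf_genes.append(spec.name)
        tf_mu_rows.append(row)
        fate_map.setdefault(spec.decision_id, []).append(spec.name)
    for i in range(config.n_null_tfs):
        tf_genes.append(f"TFNULL_{i + 1:02d}")
        tf_mu_rows.append(np.full(n_samples, np.log(config.null_tf_mean)))

    all_genes = genes + tf_genes
    mu = np.vstack([mu] + [r[None, :] for r in tf_mu_rows]) if tf_mu_rows else mu
    n_total = len(all_genes)

    s = np.exp(rng.normal(0.0, config.library_log_sd, n_samples))
    mean = np.exp(mu) * s[None, :]
    if config.dispersion > 0:
        phi = np.exp(rng.normal(np.log(config.dispersion),
                                config.dispersion_log_sd, n_total))
        shape = 1.0 / phi
        lam = rng.gamma(shape[:, None], mean * phi[:, None])
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=all_genes,
                             columns=samples)
    meta = pd.DataFrame(
        {
            "cell_type": np.repeat(celltypes, config.n_individuals),
            "individual": individuals * len(celltypes),
        },
        index=pd.Index(samples, name="sample"),
    )
    cm = CountMatrix(counts=counts_df, metadata=meta)
    truth = GroundTruth(
        module_labels=pd.Series(
            np.concatenate([module_labels, np.zeros(len(tf_genes), dtype=int)]),
            index=all_genes, name="module",
        ),
        module_celltypes={
            i + 1: spec.celltypes for i, spec in enumerate(config.modules)
        },
        module_activity=pd.DataFrame(activity, index=samples).T,
        fate_tfs=fate_map,
        tf_list=tf_genes,
        tfbs_plants=list(config.tfbs_plants),
        term_plants=list(config.term_plants),
        tree=default_tree_dict(),
    )
    return cm, truth


def simulate_annotation(truth: GroundTruth, config: SimulationConfig,
                        seed: int | None = None):
    """TSS table, peak BED rows and GMT terms with planted enrichments.

    Genes sit on one synthetic chromosome, spaced ``config.gene_spacing``
    apart with alternating strands (so promoter windows never cross the
    origin). For each planted (TF, module), peaks land inside promoters of
    module genes with the foreground probability and inside other promoters
    with the background probability. Returns ``(tss, peaks, gmt)`` as two
    DataFrames and a GMT-style dict.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = [g for g in truth.module_labels.index if not g.startswith("TF")]
    n = len(genes)
    coords = config.gene_spacing * (np.arange(n) + 2)  # first TSS at 20 kb
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    tss = pd.DataFrame(
        {"gene": genes, "chrom": "chrSim", "strand": strands, "tss": coords}
    )

    labels = truth.module_labels.loc[genes].to_numpy()
    peak_rows = []

    def add_peaks(tf: str, hit: np.ndarray) -> None:
        # a 200 bp peak centered on the TSS always overlaps the promoter
        for i in np.flatnonzero(hit):
            c = int(coords[i])
            peak_rows.append({"tf": tf, "chrom": "chrSim",
                              "start": c - 100, "end": c + 100})

    for plant in truth.tfbs_plants:
        in_mod = labels == plant.module
        prob = np.where(in_mod, plant.foreground, plant.background)
        add_peaks(plant.tf, rng.random(n) < prob)
    for i in range(config.n_background_tfbs):
        add_peaks(f"TFBG_{i + 1:02d}", rng.random(n) < config.background_tfbs_rate)
    peaks = pd.DataFrame(peak_rows, columns=["tf", "chrom", "start", "end"])

    gmt: dict[str, dict] = {}
    garr = np.asarray(genes)
    for plant in truth.term_plants:
        in_mod = labels == plant.module
        prob = np.where(in_mod, plant.foreground, plant.background)
        members = garr[rng.random(n) < prob]
        gmt[plant.term] = {"description": f"planted in module {plant.module}",
                           "genes": set(members)}
    for i in range(config.n_background_terms):
        members = garr[rng.random(n) < config.background_term_rate]
        gmt[f"TERMBG_{i + 1:02d}"] = {"description": "background term",
                                      "genes": set(members)}
    return tss, peaks, gmt


def write_fixtures(out_dir, config: SimulationConfig | None = None):
    """Write counts.tsv, metadata.tsv, tss.tsv, peaks.bed, terms.gmt, truth.json."""
    import json
    from pathlib import Path

    if config is None:
        config = SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(config)
    tss, peaks, gmt = simulate_annotation(truth, config)
    cm.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
    cm.metadata.reset_index().to_csv(out / "metadata.tsv", sep="\t", index=False)
    tss.to_csv(out / "tss.tsv", sep="\t", index=False)
    peaks[["chrom", "start", "end", "tf"]].to_csv(
        out / "peaks.bed", sep="\t", index=False, header=False
    )
    with open(out / "terms.gmt", "w") as fh:
        for term, rec in gmt.items():
            fh.write("\t".join([term, rec["description"], *sorted(rec["genes"])]) + "\n")
    with open(out / "tree.json", "w") as fh:
        json.dump(truth.tree, fh, indent=1)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "module_labels": truth.module_labels.to_dict(),
                "module_celltypes": {
                    str(k): list(v) for k, v in truth.module_celltypes.items()
                },
                "fate_tfs": truth.fate_tfs,
                "tf_list": truth.tf_list,
                "tfbs_plants": [vars(p) for p in truth.tfbs_plants],
                "term_plants": [vars(p) for p in truth.term_plants],
            },
            fh,
        )
    return cm, truth
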
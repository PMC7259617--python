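# Methods

## Count model and normalization

Input is a genes × samples matrix of raw read counts with one metadata row
per sample (cell type, individual). Low-expression filtering keeps gene *g*
iff CPM_gj = y_gj / L_j · 10⁶ ≥ *t* in at least *m* samples, computed on the
unfiltered library sizes L_j. Defaults: *t* = 1 CPM and *m* = the smallest
cell-type group size, so a gene expressed in only one population survives.
Filtering is idempotent by construction.

TMM factors follow the Robinson–Oshlack weighted trimmed mean. For sample
*k* against reference *r* (the sample whose upper-quartile CPM is closest to
the mean upper-quartile), genes with a zero count in either sample are
excluded pairwise; the per-gene log2 ratio M_g and abundance A_g are
trimmed — 30 % of the M distribution and 5 % of the A distribution from
each tail, rank-based with average ties — and the surviving M values are
averaged with inverse delta-method variance weights
w_g = (L_k − y_gk)/(L_k y_gk) + (L_r − y_gr)/(L_r y_gr). The factor is
2^(weighted mean); factors are rescaled to geometric mean 1, which also
makes them invariant to a global rescaling of all columns. A cross-check
test verifies agreement with the Bioconductor edgeR implementation on a
small matrix to 1e−6. Expression is log2-CPM with a prior count:
log2((y + 0.5)/(L_j f_j + 1)·10⁶). Precision (voom-style) observation
weights are deliberately not computed — no downstream stage uses them.

## Global structure

PCA operates on the samples × genes matrix with each gene centered (scaling
optional, off by default); components come from the SVD and variance
fractions from σ_k²/Σσ². Component signs are fixed by making the
largest-magnitude sample score positive, which is invariant to gene order.
The multivariate variance explained by cell type standardizes each gene to
mean 0/variance 1, then sums one-way-ANOVA between-group sums of squares
over genes and divides by the summed total SS. Under random labels its
expectation is (C−1)/(n−1); a calibration test checks this. Sample
clustering uses the Pearson correlation distance d = 1 − r between sample
profiles (not (1−r)/2; the conventional reading) with complete linkage by
default, exported as Newick with branch lengths equal to merge-height
differences.

## Signed network and modules

Adjacency is a_ij = ((1+r_ij)/2)^β with Pearson r across samples and β = 12,
diagonal forced to 1. The soft-threshold scan reports, per β, the mean
connectivity and a scale-free fit index: connectivities are binned into ten
equal-width bins, and log10 bin frequency is regressed on log10 bin-mean
connectivity; R² is signed by −sign(slope). (Equal-occupancy binning would
make the bin frequencies constant and the regression degenerate, so
equal-width binning — the convention of the method this scan follows — is
used.)

Topological overlap is t_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
l_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu, computed by matrix
multiplication and checked against a brute-force triple loop to 1e−12.

Genes are clustered by average linkage on 1 − t. The dynamic cut is a
simplified variant of the published hybrid algorithm, in three steps:

1. **Static cut** at a deep-split-dependent fraction of the maximum merge
   height ({0: 0.95, 1: 0.97, 2: 0.99, 3: 0.995, 4: 0.999}); larger
   deepSplit cuts lower and yields more, smaller clusters.
2. **Core reduction.** The TOM denominator min(k_i, k_j) inflates the
   similarity between a tight module and a weakly connected outside gene
   whose few edges happen to point into it, so a static cut attaches a halo
   of such genes to every module. Within each cluster, a gene is kept only
   if its mean TOM similarity to the rest of the cluster is at least half
   (``core_ratio = 0.5``) the cluster's median such similarity, iterated to
   a fixed point. This plays the role of the core/periphery analysis in the
   full published algorithm; dropped genes become unassigned (label 0)
   rather than being reassigned to another cluster.
3. **Minimum size.** Clusters below minClusterSize (default 20) are
   dissolved to label 0; surviving modules are relabeled 1..M by decreasing
   size.

Close modules are merged iteratively: while any pair of module eigengenes
has dissimilarity 1 − cor < cutHeight (default 0.05), the closest pair is
merged and eigengenes recomputed. The procedure never increases the module
count and is idempotent.

A module eigengene is PC1 of the samples × module-genes matrix after
per-gene standardization, rescaled to unit variance and sign-anchored to
correlate positively with the module's mean standardized expression.
Module–cell-type association correlates eigengenes with one-vs-rest binary
indicators; p-values use the Student transform t = r√(n−2)/√(1−r²) on n−2
df, two-sided, with p = 0 at |r| = 1. Raw p-values are thresholded at 0.05
downstream; BH-adjusted values are emitted alongside for transparency but
are not used for the threshold.

## Module gene lists and enrichment

TEGs: gene means are computed over all samples of the module's associated
cell types (pooled when several cell types are associated); the threshold is
the 98th percentile of these means over the whole filtered gene universe,
and module genes at or above it are returned. MRGs: gene contribution to
PC1 is the squared unit-norm loading; genes are ranked (ties by id) and the
shortest prefix accumulating 20 % of PC1 is returned. The top-20 cap is
available but disabled by default. Term enrichment and promoter-TFBS
enrichment both use the exact hypergeometric upper tail P(X ≥ k) with
universe N, annotated K, module n, overlap k, and fold = (k/n)/(K/N); term
reporting filters at fold ≥ 2 and p < 0.05, TFBS reporting at p < 0.05.

## Promoters and peak overlap

Promoters are −1000/+500 around the TSS on the gene's strand: + strand
[TSS−1000, TSS+500] 1-based inclusive, − strand mirrored, emitted 0-based
half-open and clipped at the chromosome origin, so every unclipped promoter
is 1,501 bp. With multiple TSS per gene the most upstream on the gene's
strand is kept (a union-of-promoters mode exists). Overlap requires ≥ 1 bp
under half-open semantics (abutting intervals do not overlap); the minimum
overlap is configurable. The enrichment universe is the genes that pass the
expression filter and have a promoter.

## Fate-TF criteria

Each internal tree node defines one decision per child (fate = that child's
leaves, contrast = its siblings' leaves). On mean raw read counts per cell
type, a TF is a candidate when (1) the average of fate cell-type means is
≥ 15× the average of contrast cell-type means, (2) every fate cell-type
mean is > 100 (strict, guarding low-count noise), and (3) the minimum fate
mean is ≥ 4× the maximum contrast mean. Criterion 1 averages per-cell-type
means ("of-means") rather than pooling samples, for symmetry with the
explicitly per-cell-type criterion 3; a pooled mode weighted by sample
counts is available. A zero contrast mean with a positive fate mean passes
the ratio criteria (ratio +∞); an all-zero TF fails. Raising any threshold
can only remove candidates.

## Synthetic study generator

The generator emulates the study design the analysis assumes: 9 cell types
× 12 individuals (108 samples), 2,000 genes, five planted modules of 40,
80, 120, 160 and 200 genes, each associated with one cell type. On the
natural-log scale μ_gj = b_g + δ_{g,c(j)} + λ_g f_{m(g),j}: baselines
b_g ~ N(log 150, 1.2²) for background genes and N(log 30, 0.5²) for module
genes; δ = +2.5 in a module's associated cell type and −2.0 elsewhere (the
module is silent off-lineage); λ_g ~ U(0.25, 0.45) and f ~ N(0,1) per "on"
sample (0 otherwise), giving within-cell-type co-variation on top of the
on/off pattern. Counts are gamma-Poisson (negative binomial) with gene-wise
dispersion φ_g ~ logN(log 0.08, 0.4²) and log-normal library factors
(sd 0.3). Six fate TFs are planted on the differentiation tree with mean
2,500 reads in their fate cell types and 10 elsewhere, alongside ten
uniformly expressed null TFs; one TF's peaks are planted into the first
module's promoters at probability 0.8 versus 0.1 background, and one GMT
term at 0.6 versus 0.1. The ground truth records, per planted module, its
per-sample *activity* δ + f — the module's total planted signal — which is
what a module eigengene estimates; eigengene recovery is scored against it.

What the generator does **not** emulate: gene-length effects, GC/composition
bias beyond library-size scaling, correlated dispersion–mean trends,
individual (donor) random effects, overlapping module membership, and any
real genomic coordinates (one synthetic chromosome, genes every 10 kb with
alternating strands). Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under the planted model, not
performance on real tissue data.

## Numerical choices and scale

Correlations use exact closed-form Pearson; adjacency entries are clipped to
[−1, 1] before powering; TOM entries to [0, 1]. Degenerate inputs fail
loudly: zero-variance genes or sample profiles, modules with fewer than two
genes, samples sharing no nonzero gene with the TMM reference. Problem
sizes in tests and the acceptance script (2,000-gene studies, 10 recovery
seeds, 100 enrichment/fate seeds, 10,000 null replicates) were chosen so
the planted effects are comfortably detectable while the whole suite runs
in about a minute on one CPU.

## Known limitations

- The dynamic tree cut is a simplified re-implementation; module boundaries
  on real data may differ from the published hybrid algorithm's.
- Missing values are rejected, not handled pairwise.
- TEG percentiles are computed on pooled associated-cell-type means; a
  per-cell-type-then-intersect variant would give different lists when a
  module is associated with several cell types.
- The fate-TF stage uses raw mean counts (configurable to CPM); with strong
  library-size imbalance between cell types, raw counts conflate depth with
  expression.
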
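"""Sample-level global structure: PCA, cell-type variance, dendrogram.

Writes PC scores, per-component variance fractions and the sample dendrogram
(Newick); prints the multivariate variance explained by cell type.
"""

from common import get_study, outdir
from immunecoex.global_structure import (
    hclust_samples,
    pca_samples,
    sample_distance,
    variance_explained_by_celltype,
)

cm, truth, nf, expr = get_study()
out = outdir()

pca = pca_samples(expr, n_components=5)
scores = pca.scores.join(cm.metadata)
scores.to_csv(out / "pca_scores.tsv", sep="\t")
with open(out / "pca_variance_fractions.tsv", "w") as fh:
    fh.write("component\tvariance_fraction\n")
    for i, v in enumerate(pca.variance_fraction, 1):
        fh.write(f"PC{i}\t{v:.6f}\n")

ve = variance_explained_by_celltype(expr, cm.metadata)
dend = hclust_samples(sample_distance(expr), linkage="complete")
(out / "sample_dendrogram.nwk").write_text(dend.to_newick() + "\n")

print(f"PC1 {100 * pca.variance_fraction[0]:.1f}%, "
      f"PC2 {100 * pca.variance_fraction[1]:.1f}% of total variance")
print(f"variance explained by cell type: {100 * ve:.1f}%")
first_leaves = dend.leaf_order[:6]
print(f"dendrogram leaf order starts: {first_leaves}")
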
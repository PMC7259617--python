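"""Prioritize fate-decision transcription factors on the differentiation tree.

Applies the three expression criteria (15-fold average, >100 mean counts in
every fate cell type, 4-fold min-fate over max-contrast) to mean raw read
counts at every branch point of the hematopoietic tree, and compares the
candidates with the planted fate TFs.
"""

from common import get_study, outdir
from immunecoex.tf_fate import mean_counts_by_celltype, prioritize_tfs, read_tree

cm, truth, nf, expr = get_study()
out = outdir()

table = mean_counts_by_celltype(cm)
tree = read_tree(truth.tree)
candidates = prioritize_tfs(table, truth.tf_list, tree,
                            fold_avg=15, min_count=100, fold_minmax=4)
candidates.to_csv(out / "fate_tf_candidates.tsv", sep="\t", index=False,
                  float_format="%.4g")

print(candidates.to_string(index=False))
expected = {(d, t) for d, tfs in truth.fate_tfs.items() for t in tfs}
found = {(r.decision, r.tf) for r in candidates.itertuples()}
print(f"planted fate TFs recovered: {len(found & expected)}/{len(expected)}; "
      f"false positives: {len(found - expected)}")
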
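"""Filter low-expressed genes, compute TMM factors and log2-CPM expression.

Writes the per-sample normalization table and reports how many genes pass
the CPM filter.
"""

import numpy as np
import pandas as pd

from common import get_study, outdir

cm, truth, nf, expr = get_study()

table = pd.DataFrame(
    {
        "cell_type": cm.metadata["cell_type"],
        "library_size": nf.library_sizes.astype(int),
        "tmm_factor": nf.factors.round(4),
        "effective_library_size": nf.effective_library_sizes.round(0).astype(int),
    }
)
table.to_csv(outdir() / "normalization_factors.tsv", sep="\t")

print(f"genes passing CPM filter: {expr.shape[0]} / {cm.counts.shape[0]}")
print(f"TMM factors: min {nf.factors.min():.3f}, max {nf.factors.max():.3f}, "
      f"geometric mean {np.exp(np.mean(np.log(nf.factors))):.6f} "
      f"(reference sample {nf.ref_sample})")
print(f"log2-CPM range: [{expr.to_numpy().min():.2f}, {expr.to_numpy().max():.2f}]")
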
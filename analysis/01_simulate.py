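"""Generate the synthetic study and write its fixture files.

Emits counts.tsv / metadata.tsv / tss.tsv / peaks.bed / terms.gmt /
tree.json / truth.json under scratch/fixtures (regenerable, not part of the
deliverable) and a small design summary under results/.
"""

import pandas as pd

from common import SCRATCH, get_config, outdir
from immunecoex.synthetic import write_fixtures

cm, truth = write_fixtures(SCRATCH / "fixtures", get_config())

summary = pd.DataFrame(
    {
        "n_genes": [cm.counts.shape[0]],
        "n_samples": [cm.counts.shape[1]],
        "n_celltypes": [cm.metadata["cell_type"].nunique()],
        "n_planted_modules": [len(truth.module_celltypes)],
        "planted_module_genes": [int((truth.module_labels > 0).sum())],
        "n_planted_fate_tfs": [sum(len(v) for v in truth.fate_tfs.values())],
        "median_library_size": [int(cm.library_sizes.median())],
    }
)
summary.to_csv(outdir() / "simulation_summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False))
print(f"fixtures written to {SCRATCH / 'fixtures'}")
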
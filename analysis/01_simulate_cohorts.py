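"""Simulate the four-cohort study conditions with planted deletion regions.

Writes probe-level log2-ratio matrices for breast (359 samples), lung (78),
melanoma (34) and Wilms (18) cohorts on four platform layouts, the planted
carrier truth, matched gene/miRNA expression datasets with planted
downregulation, annotations and synthetic gene sets.
"""

from common import get_config
from mdr21 import pipeline as pl

cfg = get_config(__doc__)
outputs = pl.run_stage("simulate", cfg)
print(f"wrote {len(outputs)} files to {cfg.out_dir}")
for p in outputs:
    print(" ", p.name)
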
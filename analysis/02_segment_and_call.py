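"""Segment every sample with CBS and call copy-number states.

Each sample's log2 ratios are cut into homogeneous-mean segments
(permutation-tested circular binary segmentation, alpha=0.01), then
classified loss/neutral/gain at +-0.2 log2.
"""

import pandas as pd

from common import get_config
from mdr21 import pipeline as pl

cfg = get_config(__doc__)
pl.run_stage("segment", cfg)
pl.run_stage("call", cfg)
calls = pd.read_csv(f"{cfg.out_dir}/calls.tsv", sep="\t")
print(calls.groupby(["cohort", "state"]).size().unstack(fill_value=0))
print(f"\n{len(calls)} called segments -> {cfg.out_dir}/calls.tsv")
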
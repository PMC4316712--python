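"""Project per-platform calls onto the 5000-anchor grid and compute
per-cohort deletion/amplification frequency profiles plus the cross-tumor
median profile."""

import pandas as pd

from common import get_config
from mdr21 import pipeline as pl

cfg = get_config(__doc__)
pl.run_stage("harmonize", cfg)
freq = pd.read_csv(f"{cfg.out_dir}/frequencies.tsv", sep="\t")
peak = freq.loc[freq.groupby("cohort")["del_freq"].idxmax()]
print("peak deletion frequency per cohort:")
print(peak[["cohort", "position", "del_freq"]].to_string(index=False))
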
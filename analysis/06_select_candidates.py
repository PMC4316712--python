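"""Select candidate tumor-suppressor genes/miRNAs: features inside a
detected deletion region that are downregulated in at least two expression
datasets of their class; run target-set over-representation for the
candidate miRNAs."""

import pandas as pd

from common import get_config
from mdr21 import pipeline as pl

cfg = get_config(__doc__)
pl.run_stage("integrate", cfg)
cand = pd.read_csv(f"{cfg.out_dir}/candidates.tsv", sep="\t")
hits = cand[cand["is_candidate"]]
print("candidates:")
print(hits.to_string(index=False))
enrich = pd.read_csv(f"{cfg.out_dir}/enrichment.tsv", sep="\t")
print("\ntarget-set over-representation:")
print(enrich.sort_values("q").to_string(index=False))
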
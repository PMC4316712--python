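"""Differential expression per dataset: quantile normalization, then Welch
t with BH FDR for the gene datasets and SAM with permutation FDR for the
miRNA datasets."""

import pandas as pd

from common import get_config
from mdr21 import pipeline as pl

cfg = get_config(__doc__)
pl.run_stage("de", cfg)
for kind in ("genes", "mirna"):
    res = pd.read_csv(f"{cfg.out_dir}/de_{kind}.tsv", sep="\t")
    down = res[(res["effect"] < 0) & (res["q"] < 0.05)]
    print(f"{kind}: {len(down)} downregulated features at q<0.05")
    print(down.groupby("dataset")["feature_id"].apply(list).to_string())
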
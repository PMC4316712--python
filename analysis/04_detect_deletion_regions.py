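"""Detect maximum-frequency deletion regions (MDRs) and summarize the
per-cohort deletion frequency of each region; plot the frequency tracks."""

import pandas as pd

from common import get_config
from mdr21 import harmonization as hz, pipeline as pl, plots
from mdr21.io import format_region_1based

cfg = get_config(__doc__)
pl.run_stage("mdr", cfg)
regions = pd.read_csv(f"{cfg.out_dir}/region_frequencies.tsv", sep="\t")
print(regions.to_string(index=False))
for row in regions.itertuples():
    print(row.region, format_region_1based(row.chrom, row.start, row.end))

freq = pd.read_csv(f"{cfg.out_dir}/frequencies.tsv", sep="\t")
grid = hz.build_anchor_grid(cfg.chrom_length, cfg.n_anchors)
profiles = []
for cohort, sub in freq.groupby("cohort", sort=False):
    profiles.append(hz.FrequencyProfile(
        grid=grid, cohort=cohort,
        del_freq=sub["del_freq"].to_numpy(),
        amp_freq=sub["amp_freq"].to_numpy(),
        n_informative=sub["n_informative"].to_numpy(),
    ))
plots.plot_frequency_profiles(profiles, f"{cfg.out_dir}/frequency_profiles.png")
print(f"plot -> {cfg.out_dir}/frequency_profiles.png")
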
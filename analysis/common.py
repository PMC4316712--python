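"""Shared run configuration for the numbered analysis scripts.

All scripts operate on the same run directory (default ``results/run``) so
they compose: each reads what the previous one wrote.
"""

import argparse
import logging

from mdr21 import pipeline as pl


def get_config(description: str) -> pl.PipelineConfig:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=21,
                        help="global seed (default 21)")
    parser.add_argument("--out", default="results/run",
                        help="run directory shared by all scripts")
    args = parser.parse_args()
    return pl.PipelineConfig(seed=args.seed, out_dir=args.out)
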
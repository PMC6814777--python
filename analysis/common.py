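"""Shared argument handling for the numbered analysis drivers.

Every driver operates on one shared run directory (default results/study) so
they can be executed in order, each consuming the previous step's outputs.
"""
import argparse
from pathlib import Path

from panelsv.pipeline import RunConfig, load_config


def parse_args(description: str) -> tuple[RunConfig, Path]:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--config", default=None, help="YAML run config")
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--outdir", default="results/study")
    args = p.parse_args()
    cfg = load_config(args.config, seed=args.seed, outdir=args.outdir)
    return cfg, Path(cfg.outdir)
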
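#!/usr/bin/env python
"""Merge per-strain calls into population variants (VCF), fold the site
frequency spectra, and compare SV classes against the labeled SNP classes."""
import pandas as pd
from common import parse_args

from panelsv.pipeline import stage_merge, stage_sfs


def main():
    cfg, out = parse_args(__doc__)
    merged = stage_merge(cfg, out)
    print(f"{len(merged)} merged variants "
          f"({sum(m.allele_count == 1 for m in merged)} singletons)")
    spectra = stage_sfs(cfg, out)
    for cat, sfs in spectra.items():
        frac1 = sfs.counts.get(1, 0) / sfs.total() if sfs.total() else float("nan")
        print(f"{cat:14s} n={sfs.total():4d} singleton fraction {frac1:.2f}")
    chisq = pd.read_csv(out / "sfs_chisq.tsv", sep="\t")
    print(chisq.to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
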
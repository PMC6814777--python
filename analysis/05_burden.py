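#!/usr/bin/env python
"""Per-gene SV burden across all founder pairings, summarized by gene-length
bin: what fraction of genes carries one or more SVs in a diploid, and how many."""
from common import parse_args

from panelsv.pipeline import stage_burden


def main():
    cfg, out = parse_args(__doc__)
    records, summary = stage_burden(cfg, out)
    frac = sum(r.multiplicity >= 1 for r in records) / len(records)
    multi = sum(r.multiplicity >= 2 for r in records)
    burdened = sum(r.multiplicity >= 1 for r in records)
    print(f"{100 * frac:.1f}% of gene x diploid combinations carry >= 1 SV; "
          f"{multi}/{burdened} burdened combinations carry several")
    print(summary.to_string(float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
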
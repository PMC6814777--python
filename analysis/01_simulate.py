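#!/usr/bin/env python
"""Simulate the founder panel: reference genome, genes, TE library, 13 derived
strain genomes with planted SVs and labeled SNPs, and the ground-truth table."""
from common import parse_args

from panelsv.pipeline import stage_simulate


def main():
    cfg, out = parse_args(__doc__)
    ref, genomes, _te, truth = stage_simulate(cfg, out)
    n_sv = sum(t.type != "snp" for t in truth)
    by_type = {}
    for t in truth:
        if t.type != "snp":
            by_type[t.type] = by_type.get(t.type, 0) + 1
    print(f"reference: {len(ref.chromosomes)} chromosomes, "
          f"{sum(map(len, ref.chromosomes.values()))/1e6:.1f} Mb, {len(ref.genes)} genes")
    print(f"panel: {len(genomes)} strains; planted {n_sv} SV loci {by_type} "
          f"and {len(truth) - n_sv} labeled SNPs")
    print(f"outputs under {out}")


if __name__ == "__main__":
    main()
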
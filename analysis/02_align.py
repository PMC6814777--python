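#!/usr/bin/env python
"""Anchor and chain every strain genome against the reference; writes one
syntenic-chain table (and the unchained secondary anchors) per strain."""
from common import parse_args

from panelsv.pipeline import stage_align


def main():
    cfg, out = parse_args(__doc__)
    chains = stage_align(cfg, out)
    for strain, chs in sorted(chains.items()):
        n_blocks = sum(len(c.blocks) for c in chs)
        minus = sum(b.strand == "-" for c in chs for b in c.blocks)
        print(f"{strain}: {len(chs)} chains, {n_blocks} blocks ({minus} minus-strand)")


if __name__ == "__main__":
    main()
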
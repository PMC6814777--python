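#!/usr/bin/env python
"""Classify SVs from the syntenic chains, annotate TE insertions, flag complex
events, and score recovery against the planted truth."""
from common import parse_args

from panelsv.pipeline import stage_call, stage_recovery


def main():
    cfg, out = parse_args(__doc__)
    per_strain = stage_call(cfg, out)
    total = sum(map(len, per_strain.values()))
    ce = [c.ce_flag for calls in per_strain.values() for c in calls]
    print(f"{total} calls across {len(per_strain)} strains; "
          f"CE flags: 0={ce.count(0)} 1={ce.count(1)} 2={ce.count(2)}")
    table = stage_recovery(cfg, out)
    print(table.to_string(float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
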
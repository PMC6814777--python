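"""SV classification from syntenic chains.

Structural differences between a strain and the reference are read off the
junctions of the syntenic chain by gap arithmetic: with reference gap ``r``
and query gap ``q`` between adjacent blocks, ``q - r`` bp of extra query
sequence is an insertion, ``r - q`` bp of missing query sequence is a
deletion, a negative reference gap (adjacent blocks re-covering reference
sequence) is a tandem duplication reported as an insertion-record CNV, and
runs of blocks on the strand opposite their flanks are inversions.  When a
junction shows both large inserted and large deleted sequence the gap
sequences are compared directly: identical sequence means the region is
simply unanchored repeat (no call), differing sequence is a
substitution-like complex event (both calls emitted and flagged CE=2).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from pydantic import BaseModel, ConfigDict

from .models import AlignmentBlock, ReferencePackage, StrainGenome, SVCall, SyntenicChain, TruthRecord


class DetectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_sv_len: int = 100
    complex_window: int = 5_000
    te_overlap_frac: float = 0.90
    svmu_n: int = 10  # anchor-merge window multiplier carried for compatibility

    def __init__(self, **data):
        super().__init__(**data)
        if not (0 < self.te_overlap_frac <= 1):
            raise ValueError("te_overlap_frac must be in (0, 1]")


def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    mismatches = sum(x != y for x, y in zip(a, b))
    return 1.0 - mismatches / len(a)


def classify_svs(
    chains: list[SyntenicChain],
    ref: ReferencePackage | dict[str, str],
    qry: StrainGenome | dict[str, str],
    cfg: DetectorConfig | None = None,
    strain_id: str | None = None,
) -> list[SVCall]:
    """Classify structural differences along each chain's junctions.

    Every emitted call has length > ``cfg.min_sv_len``; sub-threshold
    differences (SNP-scale gaps) emit nothing.  CE flags are assigned later
    by :func:`flag_complex`.
    """
    cfg = cfg or DetectorConfig()
    ref_seqs = ref.chromosomes if isinstance(ref, ReferencePackage) else ref
    if isinstance(qry, StrainGenome):
        qry_seqs = qry.chromosomes
        strain_id = strain_id or qry.strain_id
    else:
        qry_seqs = qry
        strain_id = strain_id or "qry"
    calls: list[SVCall] = []
    for chain in chains:
        blocks = chain.blocks
        if not blocks:
            continue
        rseq = ref_seqs[chain.ref_chrom]
        qseq = qry_seqs.get(chain.qry_seq, "") if isinstance(qry_seqs, dict) else ""
        plus = sum(b.ref_span for b in blocks if b.strand == "+")
        minus = sum(b.ref_span for b in blocks if b.strand == "-")
        majority = "+" if plus >= minus else "-"
        calls += _process_blocks(
            blocks, rseq, qseq, chain.ref_chrom, chain.qry_seq, strain_id, cfg, majority
        )
    calls.sort(key=lambda c: (c.ref_chrom, c.ref_start, c.type))
    return calls


def _process_blocks(blocks, rseq, qseq, ref_chrom, qry_name, strain_id, cfg, majority, depth=0):
    """Inversion runs plus junction arithmetic over one ordered block list.

    Substitution-like junctions (large r and q) are re-anchored locally and
    classified recursively: sequence that the global chain left unanchored
    because of repeat multiplicity is unique within the junction, so a local
    chain resolves the true events.  Only a junction with genuinely
    unalignable gap sequence is emitted as a flagged insertion+deletion pair.
    """
    min_len = cfg.min_sv_len
    calls: list[SVCall] = []

    # inversions: maximal runs of minority-strand blocks
    i = 0
    while i < len(blocks):
        if blocks[i].strand != majority:
            j = i
            while j + 1 < len(blocks) and blocks[j + 1].strand != majority:
                j += 1
            run = blocks[i : j + 1]
            rs, re_ = run[0].ref_start, max(b.ref_end for b in run)
            if re_ - rs > min_len:
                calls.append(
                    SVCall(
                        strain_id, "inversion", ref_chrom, rs, re_,
                        qry_name, min(b.qry_start for b in run), max(b.qry_end for b in run),
                        re_ - rs,
                    )
                )
            i = j + 1
        else:
            i += 1

    for b1, b2 in zip(blocks, blocks[1:]):
        r = b2.ref_start - b1.ref_end
        q = b2.qry_start - b1.qry_end
        if r < -min_len:
            # tandem duplication: reference interval covered twice
            dup_len = min(b1.ref_end, b2.ref_end) - b2.ref_start
            spacer = q > min_len
            calls.append(
                SVCall(
                    strain_id, "duplication", ref_chrom,
                    b2.ref_start, b2.ref_start + dup_len,
                    qry_name, b2.qry_start, b2.qry_start + dup_len,
                    dup_len, copy_number=2, cnv=True, complex_hint=spacer,
                )
            )
            if spacer:
                calls.append(
                    SVCall(
                        strain_id, "insertion", ref_chrom, b1.ref_end, b1.ref_end,
                        qry_name, b1.qry_end, b2.qry_start, q, complex_hint=True,
                    )
                )
        elif r > min_len and q > min_len:
            ref_gap = rseq[b1.ref_end : b2.ref_start]
            qry_gap = qseq[b1.qry_end : b2.qry_start] if qseq else ""
            if _identity(ref_gap, qry_gap) >= 0.95:
                continue  # unanchored but matching sequence (repeat), no event
            sub = _local_realign(b1, b2, ref_gap, qry_gap, ref_chrom, qry_name) if depth == 0 else None
            if sub:
                calls += _process_blocks(
                    [b1, *sub, b2], rseq, qseq, ref_chrom, qry_name, strain_id, cfg,
                    majority, depth=1,
                )
                continue
            calls.append(
                SVCall(
                    strain_id, "deletion", ref_chrom, b1.ref_end, b2.ref_start,
                    qry_name, b1.qry_end, b1.qry_end, r, complex_hint=True,
                )
            )
            calls.append(
                SVCall(
                    strain_id, "insertion", ref_chrom, b1.ref_end, b1.ref_end,
                    qry_name, b1.qry_end, b2.qry_start, q, complex_hint=True,
                )
            )
        elif q - r > min_len:
            calls.append(
                SVCall(
                    strain_id, "insertion", ref_chrom, b1.ref_end, b1.ref_end,
                    qry_name, b1.qry_end, b2.qry_start, q - r,
                )
            )
        elif r - q > min_len:
            calls.append(
                SVCall(
                    strain_id, "deletion", ref_chrom, b1.ref_end, b2.ref_start,
                    qry_name, b1.qry_end, b2.qry_start, r - q,
                )
            )
    return calls


def _local_realign(b1, b2, ref_gap: str, qry_gap: str, ref_chrom: str, qry_name: str):
    """Chain the two gap sequences against each other, without a repeat
    multiplicity cap (the repeat is unique within the junction), and lift the
    local blocks to global coordinates."""
    from .align import chain_anchors, find_anchors

    if not ref_gap or not qry_gap:
        return None
    anchors = find_anchors(ref_gap, qry_gap, 20, ref_chrom, qry_name)
    chains, _sec = chain_anchors(anchors, max_multiplicity=None, min_anchor_len=40)
    if not chains or not chains[0].blocks:
        return None
    out = []
    for lb in chains[0].blocks:
        out.append(
            AlignmentBlock(
                ref_chrom, b1.ref_end + lb.ref_start, b1.ref_end + lb.ref_end,
                qry_name, b1.qry_end + lb.qry_start, b1.qry_end + lb.qry_end, lb.strand,
            )
        )
    return out


def annotate_te_insertions(
    calls: list[SVCall],
    qry_te_annotation: list[tuple[str, int, int, str]],
    te_overlap_frac: float = 0.90,
    chrom_names: set[str] | None = None,
) -> list[SVCall]:
    """Retype insertions as TE insertions by annotation overlap.

    An insertion whose query interval contains at least ``te_overlap_frac``
    of a TE annotation's length becomes a TE_insertion carrying that family;
    all qualifying families are appended.  Annotations on sequence names
    outside ``chrom_names`` (when given) raise.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, family in qry_te_annotation:
        if chrom_names is not None and chrom not in chrom_names:
            raise ValueError(f"TE annotation on unknown sequence {chrom!r}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, family)
    for call in calls:
        if call.type != "insertion" or call.cnv:
            continue
        tree = trees.get(call.qry_chrom)
        if tree is None:
            continue
        fams = []
        for iv in sorted(tree.overlap(call.qry_start, call.qry_end)):
            ov = min(iv.end, call.qry_end) - max(iv.begin, call.qry_start)
            if ov >= te_overlap_frac * (iv.end - iv.begin):
                fams.append(iv.data)
        if fams:
            call.type = "TE_insertion"
            call.te_families = fams
    return calls


def flag_complex(calls: list[SVCall], cfg: DetectorConfig | None = None) -> list[SVCall]:
    """Assign CE flags: 2 = complex junction, 1 = within the complex window
    of a CE=2 call, 0 = simple."""
    cfg = cfg or DetectorConfig()
    complex_footprints: dict[str, list[tuple[int, int]]] = {}
    for c in calls:
        c.ce_flag = 2 if c.complex_hint else 0
        if c.complex_hint:
            complex_footprints.setdefault(c.ref_chrom, []).append((c.ref_start, c.ref_end))
    for c in calls:
        if c.ce_flag == 2:
            continue
        for s, e in complex_footprints.get(c.ref_chrom, ()):
            gap = max(s - c.ref_end, c.ref_start - e, 0)
            if gap <= cfg.complex_window:
                c.ce_flag = 1
                break
    return calls


@dataclass
class _TruthUnit:
    record: TruthRecord
    strain: str
    matched: bool = False


def score_recovery(
    calls: list[SVCall],
    truth: list[TruthRecord],
    pos_tol: int = 100,
    len_tol: float = 0.10,
) -> pd.DataFrame:
    """Per-type precision/recall of calls against per-carrier truth units.

    A call matches a truth record iff same strain, type and chromosome,
    breakpoints within ``pos_tol`` bp and length within ``len_tol``
    (fractional); matching is greedy one-to-one by breakpoint distance.
    """
    units = [
        _TruthUnit(t, strain)
        for t in truth
        if t.type != "snp"
        for strain in sorted(t.carriers)
    ]
    index: dict[tuple, list[_TruthUnit]] = {}
    for u in units:
        index.setdefault((u.strain, u.record.type, u.record.ref_chrom), []).append(u)

    pairs = []
    for ci, c in enumerate(calls):
        for u in index.get((c.strain_id, c.type, c.ref_chrom), ()):
            t = u.record
            dist = max(abs(c.ref_start - t.ref_start), abs(c.ref_end - t.ref_end))
            if dist <= pos_tol and abs(c.length - t.length) <= len_tol * t.length:
                pairs.append((dist, ci, u))
    pairs.sort(key=lambda p: p[0])
    call_matched = [False] * len(calls)
    for _dist, ci, u in pairs:
        if not call_matched[ci] and not u.matched:
            call_matched[ci] = True
            u.matched = True

    types = sorted({t.type for t in truth if t.type != "snp"} | {c.type for c in calls})
    rows = []
    for sv_type in types + ["overall"]:
        if sv_type == "overall":
            n_calls = len(calls)
            n_truth = len(units)
            m_calls = sum(call_matched)
            m_truth = sum(u.matched for u in units)
        else:
            sel = [i for i, c in enumerate(calls) if c.type == sv_type]
            usel = [u for u in units if u.record.type == sv_type]
            n_calls, n_truth = len(sel), len(usel)
            m_calls = sum(call_matched[i] for i in sel)
            m_truth = sum(u.matched for u in usel)
        rows.append(
            dict(
                type=sv_type,
                n_calls=n_calls,
                n_truth=n_truth,
                matched_calls=m_calls,
                matched_truth=m_truth,
                precision=m_calls / n_calls if n_calls else float("nan"),
                recall=m_truth / n_truth if n_truth else float("nan"),
            )
        )
    return pd.DataFrame(rows).set_index("type")
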
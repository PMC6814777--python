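"""Anchor-based whole-genome alignment for desk-scale assemblies.

The aligner finds maximal exact matches (MEMs) of length >= ``min_len`` on
both strands via exact 2-bit k-mer seeding and diagonal-run merging, then
chains them into a single strand-aware syntenic chain per (reference
chromosome, query sequence) pair.  Anchors hitting over-represented
reference intervals are dropped before chaining (uniqueness stands in for
repeat masking); dropped and unchained anchors are retained separately so
duplicated sequence remains visible to the SV caller.
"""
from __future__ import annotations

import numpy as np

from .models import AlignmentBlock, Anchor, ReferencePackage, SyntenicChain
from .seqs import encode, kmer_hashes, revcomp

DEFAULT_MIN_ANCHOR_LEN = 20
DEFAULT_MAX_JOIN_GAP = 10_000
DEFAULT_GAP_PENALTY = 0.01
DEFAULT_MAX_MULTIPLICITY = 2
QRY_OVERLAP_SLACK = 50  # bp of query overlap tolerated between chained blocks


class AnchorIndex:
    """Sorted k-mer index of one reference sequence, reusable across queries."""

    def __init__(self, ref_seq: str, min_len: int = DEFAULT_MIN_ANCHOR_LEN, ref_chrom: str = "ref"):
        if min_len < 8:
            raise ValueError("min_len must be >= 8")
        self.min_len = min_len
        self.k = min(min_len, 32)
        self.ref_chrom = ref_chrom
        self.ref_len = len(ref_seq)
        codes = encode(ref_seq)
        h, valid = kmer_hashes(codes, self.k)
        pos = np.nonzero(valid)[0].astype(np.int64)
        hv = h[valid]
        order = np.argsort(hv, kind="stable")
        self._h = hv[order]
        self._pos = pos[order]

    def _mems(self, qcodes: np.ndarray, max_seed_hits: int) -> np.ndarray:
        """(ref_start, qry_start, length) rows of all MEMs >= min_len."""
        k = self.k
        h, valid = kmer_hashes(qcodes, k)
        if h.size == 0 or self._h.size == 0:
            return np.empty((0, 3), dtype=np.int64)
        qpos = np.nonzero(valid)[0].astype(np.int64)
        hq = h[valid]
        lo = np.searchsorted(self._h, hq, side="left")
        hi = np.searchsorted(self._h, hq, side="right")
        cnt = hi - lo
        keep = (cnt > 0) & (cnt <= max_seed_hits)
        lo, cnt, qpos = lo[keep], cnt[keep], qpos[keep]
        total = int(cnt.sum())
        if total == 0:
            return np.empty((0, 3), dtype=np.int64)
        base = np.repeat(np.cumsum(cnt) - cnt, cnt)
        idx = np.repeat(lo, cnt) + (np.arange(total, dtype=np.int64) - base)
        rp = self._pos[idx]
        qp = np.repeat(qpos, cnt)
        diag = qp - rp
        order = np.lexsort((rp, diag))
        rp, qp, diag = rp[order], qp[order], diag[order]
        new_run = np.empty(total, dtype=bool)
        new_run[0] = True
        new_run[1:] = (diag[1:] != diag[:-1]) | (rp[1:] != rp[:-1] + 1)
        starts = np.nonzero(new_run)[0]
        ends = np.append(starts[1:], total)
        lengths = (ends - starts) + k - 1
        out = np.column_stack((rp[starts], qp[starts], lengths))
        return out[lengths >= self.min_len]

    def anchors(self, qry_seq: str, qry_name: str = "qry", max_seed_hits: int = 64) -> list[Anchor]:
        """All maximal exact matches >= min_len on both strands."""
        result: list[Anchor] = []
        qc = encode(qry_seq)
        for rs, qs, ln in self._mems(qc, max_seed_hits):
            result.append(
                Anchor(self.ref_chrom, int(rs), int(rs + ln), qry_name, int(qs), int(qs + ln), "+")
            )
        rc = encode(revcomp(qry_seq))
        qlen = len(qry_seq)
        for rs, qs, ln in self._mems(rc, max_seed_hits):
            result.append(
                Anchor(
                    self.ref_chrom,
                    int(rs),
                    int(rs + ln),
                    qry_name,
                    int(qlen - qs - ln),
                    int(qlen - qs),
                    "-",
                )
            )
        result.sort(key=lambda a: (a.ref_start, a.qry_start, a.strand))
        return result


def find_anchors(
    ref_seq: str,
    qry_seq: str,
    min_len: int = DEFAULT_MIN_ANCHOR_LEN,
    ref_chrom: str = "ref",
    qry_name: str = "qry",
    max_seed_hits: int = 64,
) -> list[Anchor]:
    """Maximal exact matches >= ``min_len`` between two sequences, both strands.

    Empty input yields an empty list.  Non-ACGT characters never match.
    """
    if not ref_seq or not qry_seq or min(len(ref_seq), len(qry_seq)) < min_len:
        return []
    return AnchorIndex(ref_seq, min_len, ref_chrom).anchors(qry_seq, qry_name, max_seed_hits)


def filter_multiplicity(anchors: list[Anchor], max_multiplicity: int = DEFAULT_MAX_MULTIPLICITY) -> tuple[list[Anchor], list[Anchor]]:
    """Split anchors into (retained, dropped) by reference-interval multiplicity.

    An anchor is dropped when more than ``max_multiplicity`` anchors (itself
    included) overlap at least half of its reference interval — the stand-in
    for repeat masking.
    """
    n = len(anchors)
    if n == 0:
        return [], []
    starts = np.array([a.ref_start for a in anchors])
    ends = np.array([a.ref_end for a in anchors])
    kept, dropped = [], []
    for i, a in enumerate(anchors):
        ov = np.minimum(ends, a.ref_end) - np.maximum(starts, a.ref_start)
        mult = int(np.count_nonzero(ov >= 0.5 * a.length))
        (kept if mult <= max_multiplicity else dropped).append(a)
    return kept, dropped


def _group_minus_runs(minus: list[Anchor], max_join_gap: int) -> list[dict]:
    """Cluster minus-strand anchors into locally collinear inverted segments.

    Within an inverted segment the query coordinate *descends* as the
    reference ascends, so anchors split by point mismatches are regrouped
    into one unit covering the segment's full extent.
    """
    units = []
    for a in sorted(minus, key=lambda a: a.ref_start):
        placed = False
        for u in units:
            if (
                -QRY_OVERLAP_SLACK <= a.ref_start - u["ref_end"] <= max_join_gap
                and -QRY_OVERLAP_SLACK <= u["qry_start"] - a.qry_end <= max_join_gap
            ):
                u["ref_end"] = max(u["ref_end"], a.ref_end)
                u["qry_start"] = min(u["qry_start"], a.qry_start)
                u["weight"] += a.length
                u["members"].append(a)
                placed = True
                break
        if not placed:
            units.append(
                dict(
                    ref_start=a.ref_start,
                    ref_end=a.ref_end,
                    qry_start=a.qry_start,
                    qry_end=a.qry_end,
                    strand="-",
                    weight=a.length,
                    members=[a],
                )
            )
    for u in units:
        u["qry_end"] = max(m.qry_end for m in u["members"])
        u["qry_start"] = min(m.qry_start for m in u["members"])
    return units


def chain_anchors(
    anchors: list[Anchor],
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    max_join_gap: int = DEFAULT_MAX_JOIN_GAP,
    max_multiplicity: int | None = DEFAULT_MAX_MULTIPLICITY,
    min_anchor_len: int | None = None,
) -> tuple[list[SyntenicChain], list[Anchor]]:
    """Select the best-scoring reference- and query-monotone chain.

    The chain maximizes total anchored length minus a linear penalty of
    ``gap_penalty`` per gap bp; adjacent blocks may not be separated by more
    than ``max_join_gap`` in either genome.  Reference overlap between
    consecutive blocks is allowed (tandem duplication signal); query overlap
    beyond a small jitter slack is not.  Returns ``(chains, secondary)``
    where ``secondary`` holds every anchor not in the chain.
    """
    if not anchors:
        return [], []
    pool = anchors
    secondary: list[Anchor] = []
    if min_anchor_len:
        secondary += [a for a in pool if a.length < min_anchor_len]
        pool = [a for a in pool if a.length >= min_anchor_len]
    if max_multiplicity is not None:
        pool, dropped = filter_multiplicity(pool, max_multiplicity)
        secondary += dropped
    if not pool:
        return [], secondary

    ref_chrom = pool[0].ref_chrom
    qry_name = pool[0].qry_seq
    units = [
        dict(
            ref_start=a.ref_start,
            ref_end=a.ref_end,
            qry_start=a.qry_start,
            qry_end=a.qry_end,
            strand="+",
            weight=a.length,
            members=[a],
        )
        for a in pool
        if a.strand == "+"
    ]
    units += _group_minus_runs([a for a in pool if a.strand == "-"], max_join_gap)
    units.sort(key=lambda u: (u["ref_start"], u["qry_start"]))

    n = len(units)
    rs = np.array([u["ref_start"] for u in units], dtype=np.int64)
    re_ = np.array([u["ref_end"] for u in units], dtype=np.int64)
    qs = np.array([u["qry_start"] for u in units], dtype=np.int64)
    qe = np.array([u["qry_end"] for u in units], dtype=np.int64)
    w = np.array([u["weight"] for u in units], dtype=np.float64)
    score = w.copy()
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        rgap = rs[i] - re_[:i]
        qgap = qs[i] - qe[:i]
        ok = (
            (re_[:i] < re_[i])
            & (qgap >= -QRY_OVERLAP_SLACK)
            & (qgap <= max_join_gap)
            & (rgap >= -max_join_gap)
            & (rgap <= max_join_gap)
        )
        if not ok.any():
            continue
        cand = score[:i] - gap_penalty * (np.maximum(rgap, 0) + np.maximum(qgap, 0))
        cand[~ok] = -np.inf
        j = int(np.argmax(cand))
        if cand[j] > 0:
            score[i] += cand[j]
            prev[i] = j

    best = int(np.argmax(score))
    path = []
    i = best
    while i >= 0:
        path.append(i)
        i = int(prev[i])
    path.reverse()
    chosen = set(path)

    blocks: list[AlignmentBlock] = []
    for i in path:
        u = units[i]
        blocks.append(
            AlignmentBlock(
                ref_chrom,
                int(u["ref_start"]),
                int(u["ref_end"]),
                qry_name,
                int(u["qry_start"]),
                int(u["qry_end"]),
                u["strand"],
            )
        )
    _trim_query_overlaps(blocks)
    for i, u in enumerate(units):
        if i not in chosen:
            secondary.extend(u["members"])
    chain = SyntenicChain(ref_chrom, qry_name, blocks, float(score[best]))
    return [chain], secondary


def _trim_query_overlaps(blocks: list[AlignmentBlock]) -> None:
    """Remove small query overlaps between consecutive blocks (anchor jitter)."""
    for a, b in zip(blocks, blocks[1:]):
        o = a.qry_end - b.qry_start
        if 0 < o < min(b.qry_end - b.qry_start, b.ref_span):
            b.qry_start += o
            if b.strand == "+":
                b.ref_start += o
            else:
                b.ref_end -= o


def scaffold_by_reference(
    contigs: dict[str, str],
    ref: ReferencePackage,
    min_anchor_len: int = DEFAULT_MIN_ANCHOR_LEN,
    n_join: int = 100,
) -> dict[str, str]:
    """Assign contigs to chromosomes by mutual-best anchored length.

    Placed contigs are ordered and oriented by reference position and joined
    with exactly ``n_join`` N characters under the chromosome's name; contigs
    without a mutual-best placement keep their own name with a "U" prefix.
    Ties on anchored length resolve to the lexicographically smaller
    chromosome name.
    """
    if not contigs:
        raise ValueError("no contigs to scaffold")
    indexes = {c: AnchorIndex(seq, min_anchor_len, c) for c, seq in ref.chromosomes.items()}
    placements: dict[str, dict] = {}
    unplaced: list[str] = []
    for name, seq in contigs.items():
        best = None
        for chrom in sorted(indexes):
            anc = indexes[chrom].anchors(seq, name)
            total = sum(a.length for a in anc)
            if total > 0 and (best is None or total > best["total"]):
                plus = sum(a.length for a in anc if a.strand == "+")
                best = dict(
                    chrom=chrom,
                    total=total,
                    ref_start=min(a.ref_start for a in anc),
                    ref_end=max(a.ref_end for a in anc),
                    strand="+" if plus >= total - plus else "-",
                )
        if best is None:
            unplaced.append(name)
        else:
            placements[name] = best

    # mutual-best: a contig keeps its region only if no stronger contig claims
    # an overlapping region of the same chromosome
    names = list(placements)
    for a in names:
        pa = placements[a]
        for b in names:
            if a == b or b not in placements:
                continue
            pb = placements[b]
            if pa["chrom"] != pb["chrom"]:
                continue
            ov = min(pa["ref_end"], pb["ref_end"]) - max(pa["ref_start"], pb["ref_start"])
            shorter = min(pa["ref_end"] - pa["ref_start"], pb["ref_end"] - pb["ref_start"])
            if ov > 0.5 * shorter and pb["total"] > pa["total"] and a in placements:
                del placements[a]
                unplaced.append(a)
                break

    out: dict[str, str] = {}
    by_chrom: dict[str, list[str]] = {}
    for name, p in placements.items():
        by_chrom.setdefault(p["chrom"], []).append(name)
    for chrom, names_ in by_chrom.items():
        names_.sort(key=lambda n: placements[n]["ref_start"])
        parts = []
        for n in names_:
            s = contigs[n]
            parts.append(revcomp(s) if placements[n]["strand"] == "-" else s)
        out[chrom] = ("N" * n_join).join(parts)
    for name in sorted(unplaced):
        out["U" + name] = contigs[name]
    return out
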
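"""Population-level SV analysis: merging, VCF, folded SFS, spectra comparison.

Per-strain calls are clustered into population variants by transitive
overlap-or-book-ended merging of same-type reference footprints (insertion
points are padded for the merge step only).  Allele count x is the number of
distinct carrier strains; the folded spectrum uses the minor count
min(x, N - x) and drops fixed variants.
"""
from __future__ import annotations

import os

import numpy as np
import pysam
from scipy import stats

from .models import FoldedSFS, MergedSV, SVCall, TruthRecord

_ALT_BY_TYPE = {
    "insertion": "<INS>",
    "TE_insertion": "<INS>",
    "deletion": "<DEL>",
    "duplication": "<DUP>",
    "inversion": "<INV>",
}
_SVTYPE = {"insertion": "INS", "TE_insertion": "INS", "deletion": "DEL",
           "duplication": "DUP", "inversion": "INV"}


def merge_calls(
    per_strain: dict[str, list[SVCall]],
    insertion_tol: int = 100,
    merge_distance: int = 0,
) -> list[MergedSV]:
    """Transitively merge same-type calls with overlapping/book-ended footprints.

    Insertion-point footprints are padded by ±``insertion_tol`` bp during
    clustering only; the merged record keeps unpadded coordinates.
    """
    items = []  # (type, chrom, padded_start, padded_end, call)
    for strain, calls in per_strain.items():
        for c in calls:
            s, e = c.ref_start, c.ref_end
            if c.type in ("insertion", "TE_insertion") and s == e:
                s, e = s - insertion_tol, e + insertion_tol
            items.append((c.type, c.ref_chrom, s, e, c))
    merged: list[MergedSV] = []
    by_group: dict[tuple[str, str], list] = {}
    for it in items:
        by_group.setdefault((it[0], it[1]), []).append(it)
    counter = 0
    for (sv_type, chrom), group in by_group.items():
        group.sort(key=lambda it: it[2])
        cluster: list = []
        cur_end = None

        def _flush():
            nonlocal counter
            if not cluster:
                return
            members = [it[4] for it in cluster]
            assert len({m.type for m in members}) == 1
            if sv_type in ("insertion", "TE_insertion") and all(
                m.ref_start == m.ref_end for m in members
            ):
                start = min(m.ref_start for m in members)
                end = start
            else:
                start = min(m.ref_start for m in members)
                end = max(m.ref_end for m in members)
            carriers = frozenset(m.strain_id for m in members)
            fams = sorted({f for m in members for f in m.te_families})
            counter += 1
            merged.append(
                MergedSV(
                    sv_id="tmp",
                    type=sv_type,
                    ref_chrom=chrom,
                    ref_start=start,
                    ref_end=end,
                    members=members,
                    carriers=carriers,
                    allele_count=len(carriers),
                    ce_flag=max((m.ce_flag or 0) for m in members),
                    te_families=fams,
                    cnv=any(m.cnv for m in members),
                    length=int(round(float(np.median([m.length for m in members])))),
                )
            )

        for it in group:
            if cur_end is None or it[2] <= cur_end + merge_distance:
                cluster.append(it)
                cur_end = it[3] if cur_end is None else max(cur_end, it[3])
            else:
                _flush()
                cluster = [it]
                cur_end = it[3]
        _flush()
    merged.sort(key=lambda m: (m.ref_chrom, m.ref_start, m.type))
    for i, m in enumerate(merged, 1):
        m.sv_id = f"MSV{i:05d}"
    return merged


def write_vcf(
    merged: list[MergedSV],
    strains: list[str],
    ref_seqs: dict[str, str],
    path: str | os.PathLike,
) -> None:
    """VCF 4.2 with symbolic ALTs and one haploid GT column per strain."""
    header = pysam.VariantHeader()
    for chrom, seq in ref_seqs.items():
        header.contigs.add(chrom, length=len(seq))
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("END", 1, "Integer", "End of the variant on the reference")
    header.info.add("SVLEN", 1, "Integer", "Signed variant length")
    header.info.add("CE", 1, "Integer", "Complex-event flag (0 simple, 1 near complex, 2 complex)")
    header.info.add("TEFAM", ".", "String", "TE families contained in the insertion")
    header.info.add("CNV", 1, "Integer", "Copy number for duplication CNVs")
    header.formats.add("GT", 1, "String", "Haploid genotype (1 = carrier)")
    for s in strains:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in merged:
            if m.ref_chrom not in ref_seqs:
                raise ValueError(f"variant on unknown chromosome {m.ref_chrom}")
            if m.ref_end > len(ref_seqs[m.ref_chrom]):
                raise ValueError(f"{m.sv_id} extends past end of {m.ref_chrom}")
            pos0 = max(m.ref_start - 1, 0)
            rec = vcf.new_record(
                contig=m.ref_chrom,
                start=pos0,
                stop=max(m.ref_end, pos0 + 1),
                alleles=(ref_seqs[m.ref_chrom][pos0], _ALT_BY_TYPE[m.type]),
                id=m.sv_id,
            )
            rec.info["SVTYPE"] = _SVTYPE[m.type]
            rec.info["SVLEN"] = -m.length if m.type == "deletion" else m.length
            rec.info["CE"] = m.ce_flag
            if m.te_families:
                rec.info["TEFAM"] = tuple(m.te_families)
            if m.cnv:
                rec.info["CNV"] = max((mm.copy_number or 2) for mm in m.members)
            for s in strains:
                rec.samples[s]["GT"] = (1,) if s in m.carriers else (0,)
            vcf.write(rec)


def read_vcf(path: str | os.PathLike) -> tuple[list[MergedSV], list[str]]:
    """Read a VCF written by :func:`write_vcf` back into merged records."""
    out: list[MergedSV] = []
    with pysam.VariantFile(str(path)) as vcf:
        strains = list(vcf.header.samples)
        for rec in vcf:
            svtype = rec.info["SVTYPE"]
            fams = list(rec.info.get("TEFAM", ()) or ())
            if svtype == "INS":
                sv_type = "TE_insertion" if fams else "insertion"
            else:
                sv_type = {"DEL": "deletion", "DUP": "duplication", "INV": "inversion"}[svtype]
            carriers = frozenset(s for s in strains if rec.samples[s]["GT"] == (1,))
            # POS holds the base before the event (symbolic-allele convention)
            start = rec.start + 1
            end = start if sv_type in ("insertion", "TE_insertion") else rec.stop
            out.append(
                MergedSV(
                    sv_id=rec.id,
                    type=sv_type,
                    ref_chrom=rec.chrom,
                    ref_start=start,
                    ref_end=end,
                    members=[],
                    carriers=carriers,
                    allele_count=len(carriers),
                    ce_flag=int(rec.info.get("CE", 0)),
                    te_families=fams,
                    cnv="CNV" in rec.info,
                    length=abs(int(rec.info["SVLEN"])),
                )
            )
    return out, strains


def folded_sfs(variants, N: int, exclude_complex: bool = True) -> FoldedSFS:
    """Fold allele counts to minor-allele classes min(x, N - x).

    ``variants`` may be MergedSV objects, (x, ce_flag) pairs, or plain allele
    counts.  Fixed variants (minor count 0) are excluded; with
    ``exclude_complex`` (default) CE>=1 variants are excluded.
    """
    counts: dict[int, int] = {}
    for v in variants:
        if isinstance(v, MergedSV):
            x, ce = v.allele_count, v.ce_flag
        elif isinstance(v, tuple):
            x, ce = v
        else:
            x, ce = int(v), 0
        if not (0 < x <= N):
            raise ValueError(f"allele count {x} outside (0, {N}]")
        if exclude_complex and ce >= 1:
            continue
        m = min(x, N - x)
        if m == 0:
            continue
        counts[m] = counts.get(m, 0) + 1
    return FoldedSFS(N, dict(sorted(counts.items())))


def truth_folded_sfs(
    truth: list[TruthRecord],
    N: int,
    types: tuple[str, ...] | None = None,
    snp_label: str | None = None,
) -> FoldedSFS:
    """Folded SFS computed directly from ground-truth carrier sets."""
    xs = [
        len(t.carriers)
        for t in truth
        if (types is None or t.type in types) and (snp_label is None or t.snp_label == snp_label)
    ]
    return folded_sfs(xs, N, exclude_complex=False)


def sfs_chisq(a: FoldedSFS, b: FoldedSFS, scheme: str = "full") -> tuple[float, int, float]:
    """Pearson chi-square between two folded spectra.

    ``full`` uses every folded class present in either spectrum (df =
    classes - 1); ``singleton`` collapses to {singleton, non-singleton}
    (1 df).  No continuity correction.
    """
    if a.N != b.N:
        raise ValueError("spectra have different sample sizes")
    classes = sorted(set(a.counts) | set(b.counts))
    if scheme == "full":
        table = np.array(
            [[a.counts.get(i, 0) for i in classes], [b.counts.get(i, 0) for i in classes]]
        )
    elif scheme == "singleton":
        table = np.array(
            [
                [a.counts.get(1, 0), sum(v for i, v in a.counts.items() if i > 1)],
                [b.counts.get(1, 0), sum(v for i, v in b.counts.items() if i > 1)],
            ]
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("fewer than two informative frequency classes; collapse classes first")
    try:
        res = stats.chi2_contingency(table, correction=False)
    except ValueError as err:
        raise ValueError("zero expected cell; collapse sparse frequency classes") from err
    return float(res.statistic), int(res.dof), float(res.pvalue)


def call_set_concordance(
    assembly_calls,
    other: list[tuple[str, int, int]],
    cnv_extension: int = 100,
) -> tuple[float, list[bool]]:
    """Fraction of assembly calls whose footprint intersects the other set.

    Duplication-CNV insertion footprints are extended by ±``cnv_extension``
    bp before intersection; plain insertion points count as 1 bp.  The
    complementary fraction (1 - detected) is the set hidden from the other
    caller.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in other:
        trees.setdefault(chrom, IntervalTree()).addi(s, max(e, s + 1))
    flags = []
    for c in assembly_calls:
        s, e = c.ref_start, c.ref_end
        if getattr(c, "cnv", False):
            s, e = s - cnv_extension, e + cnv_extension
        if e == s:
            e = s + 1
        tree = trees.get(c.ref_chrom)
        flags.append(bool(tree is not None and tree.overlap(s, e)))
    fraction = sum(flags) / len(flags) if flags else 0.0
    return fraction, flags
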
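"""Readers and writers for the pipeline's file interfaces.

Internal coordinates are 0-based half-open; GFF3, VCF and RepeatMasker .out
are 1-based inclusive on disk, BED/PAF/coords-TSV are 0-based half-open.
"""
from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pyfaidx

from .models import AlignmentBlock, GeneModel, MergedSV, SVCall, TruthRecord

TRUTH_COLUMNS = [
    "sv_id",
    "type",
    "ref_chrom",
    "ref_start",
    "ref_end",
    "length",
    "carriers",
    "te_family",
    "spacer_length",
    "snp_label",
]

COORDS_COLUMNS = [
    "ref_chrom",
    "ref_start",
    "ref_end",
    "qry_seq",
    "qry_start",
    "qry_end",
    "strand",
    "identity",
]


def write_fasta(path: str | os.PathLike, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def write_gff3(path: str | os.PathLike, genes: list[GeneModel], chrom_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, ln in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {ln}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpanelsv\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
            )


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"gene{lineno}")
            genes.append(GeneModel(gene_id, parts[0], int(parts[3]) - 1, int(parts[4])))
    return genes


def write_bed(path: str | os.PathLike, rows: list[tuple]) -> None:
    """Rows of (chrom, start, end, name[, ...]) in 0-based half-open coords."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 3:
                raise ValueError(f"{path}:{lineno}: BED row has fewer than 3 columns")
            out.append((p[0], int(p[1]), int(p[2]), *p[3:]))
    return out


_RM_HEADER = (
    "   SW  perc perc perc  query     position in query     matching repeat       position in repeat\n"
    "score  div. del. ins.  sequence  begin end    (left)   repeat   class/family begin end  (left)  ID\n"
    "\n"
)


def write_rm_out(path: str | os.PathLike, rows: list[tuple[str, int, int, str]]) -> None:
    """RepeatMasker .out dialect; rows are (chrom, start, end, family) 0-based half-open."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, (chrom, start, end, family) in enumerate(rows, 1):
            ln = end - start
            fh.write(
                f" 10000  0.0  0.0  0.0  {chrom}  {start + 1} {end}  (0)  +  {family}  "
                f"Unknown  1  {ln}  (0)  {i}\n"
            )


def read_rm_out(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header / blank lines
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: malformed RepeatMasker row")
            out.append((parts[4], int(parts[5]) - 1, int(parts[6]), parts[9]))
    return out


def write_coords_tsv(path: str | os.PathLike, blocks: list[AlignmentBlock]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COORDS_COLUMNS) + "\n")
        for b in blocks:
            fh.write(
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.qry_seq}\t"
                f"{b.qry_start}\t{b.qry_end}\t{b.strand}\t{b.identity:g}\n"
            )


def read_coords_tsv(path: str | os.PathLike, known_chroms: set[str] | None = None) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            return []
        header = first.rstrip("\n").split("\t")
        if header != COORDS_COLUMNS:
            raise ValueError(f"{path}:1: unexpected coords header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) != 8 or p[6] not in "+-":
                raise ValueError(f"{path}:{lineno}: malformed coords row")
            if known_chroms is not None and p[0] not in known_chroms:
                raise ValueError(f"{path}:{lineno}: unknown reference chromosome {p[0]!r}")
            blocks.append(
                AlignmentBlock(p[0], int(p[1]), int(p[2]), p[3], int(p[4]), int(p[5]), p[6], float(p[7]))
            )
    return blocks


def read_paf(path: str | os.PathLike, known_chroms: set[str] | None = None) -> list[AlignmentBlock]:
    """PAF rows as alignment blocks: target = reference, query coords ascending."""
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12 or p[4] not in "+-":
                raise ValueError(f"{path}:{lineno}: malformed PAF row")
            qname, qstart, qend, strand = p[0], int(p[2]), int(p[3]), p[4]
            tname, tstart, tend = p[5], int(p[7]), int(p[8])
            if known_chroms is not None and tname not in known_chroms:
                raise ValueError(f"{path}:{lineno}: unknown reference chromosome {tname!r}")
            nmatch, alen = int(p[9]), int(p[10])
            blocks.append(
                AlignmentBlock(tname, tstart, tend, qname, qstart, qend, strand,
                               nmatch / alen if alen else 0.0)
            )
    return blocks


def read_alignments(path: str | os.PathLike, dialect: str = "coords", known_chroms: set[str] | None = None) -> list[AlignmentBlock]:
    if dialect == "coords":
        return read_coords_tsv(path, known_chroms)
    if dialect == "paf":
        return read_paf(path, known_chroms)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_truth_tsv(path: str | os.PathLike, truth: list[TruthRecord]) -> None:
    rows = [
        dict(
            sv_id=t.sv_id,
            type=t.type,
            ref_chrom=t.ref_chrom,
            ref_start=t.ref_start,
            ref_end=t.ref_end,
            length=t.length,
            carriers=",".join(sorted(t.carriers)),
            te_family=t.te_family or "",
            spacer_length=t.spacer_length,
            snp_label=t.snp_label or "",
        )
        for t in truth
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | os.PathLike) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"te_family": str, "snp_label": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(
            TruthRecord(
                sv_id=r.sv_id,
                type=r.type,
                ref_chrom=r.ref_chrom,
                ref_start=int(r.ref_start),
                ref_end=int(r.ref_end),
                length=int(r.length),
                carriers=frozenset(str(r.carriers).split(",")),
                te_family=r.te_family or None,
                spacer_length=int(r.spacer_length),
                snp_label=r.snp_label or None,
            )
        )
    return out


CALL_COLUMNS = [
    "strain_id", "type", "ref_chrom", "ref_start", "ref_end",
    "qry_chrom", "qry_start", "qry_end", "length",
    "copy_number", "te_families", "ce_flag", "cnv", "complex_hint",
]


def write_calls_tsv(path: str | os.PathLike, calls: list[SVCall]) -> None:
    rows = [
        dict(
            strain_id=c.strain_id, type=c.type, ref_chrom=c.ref_chrom,
            ref_start=c.ref_start, ref_end=c.ref_end, qry_chrom=c.qry_chrom,
            qry_start=c.qry_start, qry_end=c.qry_end, length=c.length,
            copy_number="" if c.copy_number is None else c.copy_number,
            te_families=",".join(c.te_families),
            ce_flag="" if c.ce_flag is None else c.ce_flag,
            cnv=int(c.cnv), complex_hint=int(c.complex_hint),
        )
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | os.PathLike) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            SVCall(
                strain_id=r.strain_id, type=r.type, ref_chrom=r.ref_chrom,
                ref_start=int(r.ref_start), ref_end=int(r.ref_end),
                qry_chrom=r.qry_chrom, qry_start=int(r.qry_start),
                qry_end=int(r.qry_end), length=int(r.length),
                copy_number=int(r.copy_number) if r.copy_number else None,
                te_families=[f for f in r.te_families.split(",") if f],
                ce_flag=int(r.ce_flag) if r.ce_flag != "" else None,
                cnv=bool(int(r.cnv)), complex_hint=bool(int(r.complex_hint)),
            )
        )
    return out


MERGED_COLUMNS = [
    "sv_id", "type", "ref_chrom", "ref_start", "ref_end", "length",
    "allele_count", "carriers", "ce_flag", "te_families", "cnv",
]


def write_merged_tsv(path: str | os.PathLike, merged: list[MergedSV]) -> None:
    rows = [
        dict(
            sv_id=m.sv_id, type=m.type, ref_chrom=m.ref_chrom,
            ref_start=m.ref_start, ref_end=m.ref_end, length=m.length,
            allele_count=m.allele_count, carriers=",".join(sorted(m.carriers)),
            ce_flag=m.ce_flag, te_families=",".join(m.te_families), cnv=int(m.cnv),
        )
        for m in merged
    ]
    pd.DataFrame(rows, columns=MERGED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_merged_tsv(path: str | os.PathLike) -> list[MergedSV]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            MergedSV(
                sv_id=r.sv_id, type=r.type, ref_chrom=r.ref_chrom,
                ref_start=int(r.ref_start), ref_end=int(r.ref_end),
                members=[], carriers=frozenset(r.carriers.split(",")),
                allele_count=int(r.allele_count), ce_flag=int(r.ce_flag),
                te_families=[f for f in r.te_families.split(",") if f],
                cnv=bool(int(r.cnv)), length=int(r.length),
            )
        )
    return out


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
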
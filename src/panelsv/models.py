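"""Shared data containers for the panel SV analysis.

Coordinates are 0-based half-open everywhere in memory; 1-based dialects
(GFF3, VCF, RepeatMasker .out) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SV_TYPES = ("TE_insertion", "insertion", "deletion", "duplication", "inversion")
VARIANT_TYPES = SV_TYPES + ("snp",)


@dataclass(frozen=True)
class GeneModel:
    """A gene span on the reference. ``length = end - start``."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span {self.gene_id}: [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferencePackage:
    """Reference chromosomes plus gene models and the TE family library.

    ``te_annotation`` lists the TE copies embedded in the reference itself
    (chrom, start, end, family); these are shared by every derived strain.
    """

    chromosomes: dict[str, str]
    genes: list[GeneModel]
    te_library: dict[str, str]
    te_annotation: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")


@dataclass
class StrainGenome:
    strain_id: str
    chromosomes: dict[str, str]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted variant (SV or labeled point variant)."""

    sv_id: str
    type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    length: int
    carriers: frozenset[str]
    te_family: Optional[str] = None
    spacer_length: int = 0
    snp_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.type}")
        if len(self.carriers) < 1:
            raise ValueError(f"{self.sv_id}: empty carrier set")


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match between reference and query.

    Query coordinates are always ascending on the forward query strand; for
    ``strand == '-'`` the anchor matches the reverse complement of the query
    interval.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_seq: str
    qry_start: int
    qry_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class AlignmentBlock:
    """A collinear alignment segment (an anchor, or merged anchors)."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_seq: str
    qry_start: int
    qry_end: int
    strand: str
    identity: float = 1.0

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class SyntenicChain:
    """Reference-monotone, query-monotone chain of blocks for one pair."""

    ref_chrom: str
    qry_seq: str
    blocks: list[AlignmentBlock]
    score: float = 0.0


@dataclass
class SVCall:
    """One per-strain structural variant call.

    Insertions are anchored at a zero-length reference interval
    (``ref_start == ref_end``); consumers pad as needed, the call itself is
    never stored padded.
    """

    strain_id: str
    type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    length: int
    copy_number: Optional[int] = None
    te_families: list[str] = field(default_factory=list)
    ce_flag: Optional[int] = None
    cnv: bool = False
    complex_hint: bool = False

    def footprint(self) -> tuple[int, int]:
        return self.ref_start, self.ref_end


@dataclass
class MergedSV:
    """A cross-strain variant cluster with its carrier set."""

    sv_id: str
    type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    members: list[SVCall]
    carriers: frozenset[str]
    allele_count: int
    ce_flag: int = 0
    te_families: list[str] = field(default_factory=list)
    cnv: bool = False
    length: int = 0


@dataclass
class FoldedSFS:
    """Minor-allele-count spectrum: counts[i] = # variants with minor count i."""

    N: int
    counts: dict[int, int]

    def total(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        for i in self.counts:
            if not (0 < i <= self.N // 2):
                raise ValueError(f"folded class {i} outside (0, N/2] for N={self.N}")
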
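"""Per-gene SV burden in synthetic diploids.

Every unordered pair of founder haplotypes is treated as one diploid; a
gene's multiplicity in a diploid is the number of unique SV mutations whose
reference footprint overlaps the gene span across the pair's two haplotypes
(a variant shared by both haplotypes counts once).  Any overlap of >= 1 bp
counts as affecting the gene (a deletion larger than the gene still affects
it); insertion breakpoints must fall strictly inside the span.  Complex
variants are included by default — they are real mutations, only the SFS
analysis excludes them — and a containment-only mode is available.
"""
from __future__ import annotations

from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, MergedSV


class DiploidBurdenRecord(NamedTuple):
    strain_a: str
    strain_b: str
    gene_id: str
    multiplicity: int


class LengthBinning:
    """Gene-length histogram bins; ascending edges, last bin open-ended."""

    def __init__(self, edges: list[int] | None = None):
        if edges is None:
            edges = list(range(0, 50_001, 5_000))  # 5-kb bins, [50 kb, inf) on top
        if sorted(edges) != list(edges) or len(edges) < 2:
            raise ValueError("bin edges must be ascending with at least two edges")
        self.edges = list(edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges)  # last bin is [edges[-1], inf)

    def bin_index(self, length: int) -> int:
        i = int(np.searchsorted(self.edges, length, side="right")) - 1
        if i < 0:
            raise ValueError(f"gene length {length} below the first bin edge")
        return min(i, self.n_bins - 1)

    def labels(self) -> list[str]:
        out = [f"[{a},{b})" for a, b in zip(self.edges, self.edges[1:])]
        out.append(f"[{self.edges[-1]},inf)")
        return out

    def partition(self, genes: list[GeneModel], burdened_ids: set[str]) -> pd.DataFrame:
        """Per-bin totals N and burdened counts K (the hypergeometric margins)."""
        rows = [dict(bin=lab, N=0, K=0) for lab in self.labels()]
        for g in genes:
            i = self.bin_index(g.length)
            rows[i]["N"] += 1
            rows[i]["K"] += g.gene_id in burdened_ids
        return pd.DataFrame(rows).set_index("bin")


def gene_sv_overlap(
    variants: list[MergedSV],
    genes: list[GeneModel],
    containment: bool = False,
    include_complex: bool = True,
    chrom_names: set[str] | None = None,
) -> dict[str, dict[str, set[str]]]:
    """Map strain -> gene_id -> set of overlapping variant ids.

    A variant affects a gene iff its reference footprint intersects the gene
    span by >= 1 bp (``containment`` demands the whole footprint inside the
    span); a zero-length insertion breakpoint must lie strictly inside the
    span.
    """
    if chrom_names is not None:
        for g in genes:
            if g.chrom not in chrom_names:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out: dict[str, dict[str, set[str]]] = {}
    for v in variants:
        if chrom_names is not None and v.ref_chrom not in chrom_names:
            raise ValueError(f"variant {v.sv_id} on unknown chromosome {v.ref_chrom}")
        if not include_complex and v.ce_flag >= 1:
            continue
        tree = trees.get(v.ref_chrom)
        if tree is None:
            continue
        if v.ref_start == v.ref_end:  # insertion breakpoint
            hits = [
                iv.data for iv in tree.at(v.ref_start)
                if iv.begin < v.ref_start < iv.end
            ]
        else:
            hits = [iv.data for iv in tree.overlap(v.ref_start, v.ref_end)]
            if containment:
                hits = [g for g in hits if g.start <= v.ref_start and v.ref_end <= g.end]
        for g in hits:
            for strain in v.carriers:
                out.setdefault(strain, {}).setdefault(g.gene_id, set()).add(v.sv_id)
    return out


def diploid_burden(
    per_strain: dict[str, dict[str, set[str]]],
    genes: list[GeneModel],
    founders: list[str],
) -> list[DiploidBurdenRecord]:
    """Multiplicity of every gene in every C(F,2) founder pairing."""
    if len(founders) != len(set(founders)):
        raise ValueError("duplicate founder ids")
    if len(founders) < 2:
        raise ValueError("need at least two founders")
    records: list[DiploidBurdenRecord] = []
    gene_ids = [g.gene_id for g in genes]
    per_gene: dict[str, dict[str, set[str]]] = {}
    for strain, gmap in per_strain.items():
        for gid, svs in gmap.items():
            per_gene.setdefault(gid, {})[strain] = svs
    empty: set[str] = set()
    for a, b in combinations(founders, 2):
        for gid in gene_ids:
            smap = per_gene.get(gid)
            if smap is None:
                records.append(DiploidBurdenRecord(a, b, gid, 0))
            else:
                records.append(
                    DiploidBurdenRecord(a, b, gid, len(smap.get(a, empty) | smap.get(b, empty)))
                )
    return records


def burden_by_length(
    records: list[DiploidBurdenRecord],
    genes: list[GeneModel],
    bins: LengthBinning | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin burdened fraction over all gene x pair combinations, plus the
    multiplicity histogram restricted to burdened combinations."""
    bins = bins or LengthBinning()
    gene_bin = {g.gene_id: bins.bin_index(g.length) for g in genes}
    labels = bins.labels()
    n_combos = np.zeros(bins.n_bins, dtype=int)
    burdened = np.zeros(bins.n_bins, dtype=int)
    mult_hist: dict[tuple[int, int], int] = {}
    for r in records:
        try:
            b = gene_bin[r.gene_id]
        except KeyError:
            raise ValueError(f"record for unknown gene {r.gene_id}") from None
        n_combos[b] += 1
        if r.multiplicity >= 1:
            burdened[b] += 1
            key = (b, r.multiplicity)
            mult_hist[key] = mult_hist.get(key, 0) + 1
    with np.errstate(invalid="ignore"):
        frac = np.where(n_combos > 0, burdened / np.maximum(n_combos, 1), np.nan)
    summary = pd.DataFrame(
        dict(bin=labels, n_combinations=n_combos, burdened=burdened, fraction=frac)
    ).set_index("bin")
    hist = pd.DataFrame(
        [dict(bin=labels[b], multiplicity=m, count=c) for (b, m), c in sorted(mult_hist.items())],
        columns=["bin", "multiplicity", "count"],
    )
    return summary, hist
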
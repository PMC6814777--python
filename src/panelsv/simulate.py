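"""Synthetic strain-panel generator.

Builds a random reference genome with genes and an embedded TE library, then
derives a panel of strain genomes by planting TE insertions, tandem
duplications (optionally spacer-separated), large indels and inversions with
a configurable rare-skewed carrier-count spectrum, plus labeled
"synonymous-like"/"nonsynonymous-like" point variants.  Every planted event
is recorded in a ground-truth table that downstream recovery is scored
against.

Default panel: 13 strains on a ~5 Mb five-chromosome genome with ~300
distinct SV loci (type mix proportioned like a real fly panel: TE
insertions dominate, inversions are rare), events spaced >= 10 kb apart so
each is an isolated, unambiguous signal.
"""
from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .models import GeneModel, ReferencePackage, StrainGenome, TruthRecord
from .seqs import random_seq, revcomp

EDGE_MARGIN = 2_000  # bp kept event-free at chromosome ends
TE_ZONE_MARGIN = 500  # bp kept event-free around reference TE copies
SNP_MARGIN = 50  # bp kept SNP-free around SV footprints


class GenomeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chrom_lengths: dict[str, int] = Field(
        default_factory=lambda: {c: 1_000_000 for c in ("X", "2L", "2R", "3L", "3R")}
    )
    n_genes: int = 600
    gene_length_median: float = 3_300.0  # lognormal median; sigma=1 gives mean ~5.4 kb
    gene_length_sigma: float = 1.0
    gene_min_length: int = 150
    n_te_families: int = 8
    te_family_length_range: tuple[int, int] = (500, 5_000)
    te_copies_per_family: int = 1

    @model_validator(mode="after")
    def _check(self):
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes < 0 or self.gene_length_median <= 0:
            raise ValueError("invalid gene spec")
        lo, hi = self.te_family_length_range
        if not (0 < lo <= hi):
            raise ValueError("TE family length range must be positive")
        return self


class SnpSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_syn: int = 1_000
    n_nonsyn: int = 1_000
    syn_sfs_alpha: float = 1.0
    nonsyn_sfs_alpha: float = 1.5


class PanelSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_strains: int = 13
    sv_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "TE_insertion": 170,
            "duplication": 27,
            "insertion": 50,
            "deletion": 51,
            "inversion": 2,
        }
    )
    sfs_alpha: float = 2.0  # carrier-count prob ~ k^-alpha over 1..n_strains
    sfs_model: list[float] | None = None  # explicit override of the above
    size_ranges: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: {
            "insertion": (150, 2_000),
            "deletion": (150, 2_000),
            "duplication": (300, 3_000),
            "inversion": (500, 5_000),
        }
    )
    min_spacing: int = 10_000
    dup_spacer_length: int = 0
    te_truncation: float = 0.0  # max fraction removed from one TE end; 0 = full copies
    complex_mode: bool = False
    n_complex_events: int = 10
    snp_spec: SnpSpec = Field(default_factory=SnpSpec)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_strains < 1:
            raise ValueError("need at least one strain")
        if any(v < 0 for v in self.sv_rates.values()):
            raise ValueError("sv_rates must be >= 0")
        for t, (lo, hi) in self.size_ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"size range for {t} must be positive")
        if self.sfs_model is not None:
            if len(self.sfs_model) != self.n_strains:
                raise ValueError("sfs_model must give one probability per carrier count 1..n_strains")
            if abs(sum(self.sfs_model) - 1.0) > 1e-8 or any(p < 0 for p in self.sfs_model):
                raise ValueError("sfs_model must be a probability distribution")
        if not (0 <= self.te_truncation < 1):
            raise ValueError("te_truncation must be in [0, 1)")
        return self

    def carrier_probs(self) -> np.ndarray:
        if self.sfs_model is not None:
            return np.asarray(self.sfs_model, dtype=float)
        k = np.arange(1, self.n_strains + 1, dtype=float)
        p = k ** (-self.sfs_alpha)
        return p / p.sum()

    def strain_names(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_strains + 1)]


def _place_nonoverlapping(rng, length, count, extent, existing, margin, tries=200):
    """Random positions for `count` intervals of size `extent` avoiding `existing`."""
    placed = []
    for _ in range(count):
        for _ in range(tries):
            s = int(rng.integers(margin, length - extent - margin))
            if all(s + extent + margin <= a or s >= b + margin for a, b, *_ in existing + placed):
                placed.append((s, s + extent))
                break
        else:
            raise ValueError("could not place interval without overlap; genome too crowded")
    return placed


def generate_reference(spec: GenomeSpec, seed: int = 0) -> ReferencePackage:
    """Random reference genome with genes and embedded TE family copies.

    Deterministic for a fixed (spec, seed).  Gene lengths are sampled from a
    lognormal with the requested median/sigma; genes are packed left to
    right with random gaps, so requesting more genic bp than a chromosome
    holds raises rather than silently truncating.
    """
    rng = np.random.default_rng(seed)
    chroms = {name: random_seq(rng, ln) for name, ln in spec.chrom_lengths.items()}

    lo, hi = spec.te_family_length_range
    te_library = {
        f"TE{i:02d}": random_seq(rng, int(rng.integers(lo, hi + 1)))
        for i in range(1, spec.n_te_families + 1)
    }

    te_annotation: list[tuple[str, int, int, str]] = []
    chrom_names = list(spec.chrom_lengths)
    weights = np.array([spec.chrom_lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for fam, fam_seq in te_library.items():
        for _ in range(spec.te_copies_per_family):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            (s, e), = _place_nonoverlapping(
                rng, spec.chrom_lengths[chrom], 1, len(fam_seq), occupied[chrom], TE_ZONE_MARGIN
            )
            occupied[chrom].append((s, e))
            chroms[chrom] = chroms[chrom][:s] + fam_seq + chroms[chrom][e:]
            te_annotation.append((chrom, s, e, fam))
    te_annotation.sort()

    genes: list[GeneModel] = []
    if spec.n_genes > 0:
        total_len = sum(spec.chrom_lengths.values())
        raw = {c: spec.n_genes * spec.chrom_lengths[c] / total_len for c in chrom_names}
        counts = {c: int(raw[c]) for c in chrom_names}
        for c in sorted(chrom_names, key=lambda c: raw[c] - counts[c], reverse=True):
            if sum(counts.values()) < spec.n_genes:
                counts[c] += 1
        gid = 0
        for chrom in chrom_names:
            n = counts[chrom]
            if n == 0:
                continue
            lengths = np.maximum(
                rng.lognormal(np.log(spec.gene_length_median), spec.gene_length_sigma, n),
                spec.gene_min_length,
            ).astype(int)
            L = spec.chrom_lengths[chrom]
            free = L - int(lengths.sum())
            if free < 0:
                raise ValueError(
                    f"infeasible gene packing on {chrom}: {lengths.sum()} genic bp requested, "
                    f"{L} available"
                )
            gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
            pos = 0
            for i in range(n):
                pos += int(gaps[i])
                gid += 1
                genes.append(GeneModel(f"G{gid:05d}", chrom, pos, pos + int(lengths[i])))
                pos += int(lengths[i])
    return ReferencePackage(chroms, genes, te_library, te_annotation)


class _Event:
    __slots__ = ("type", "chrom", "start", "end", "length", "payload", "family",
                 "spacer", "carriers", "ins_len")

    def __init__(self, type_, length, payload=None, family=None, spacer=0, ins_len=0):
        self.type = type_
        self.length = length
        self.payload = payload
        self.family = family
        self.spacer = spacer
        self.ins_len = ins_len  # substitution replacement length (complex mode)
        self.chrom = None
        self.start = None
        self.end = None
        self.carriers = None

    @property
    def extent(self) -> int:
        return 0 if self.type in ("insertion", "TE_insertion") else self.length


def plant_variants(
    ref: ReferencePackage, panel: PanelSpec, seed: int | None = None
) -> tuple[list[StrainGenome], dict[str, list[tuple[str, int, int, str]]], list[TruthRecord]]:
    """Derive strain genomes from the reference by planting the panel's variants.

    Returns (strain genomes, per-strain TE annotations in strain coordinates,
    truth records).  Carriers contain the edited sequence; non-carriers match
    the reference at every planted locus.  Raises when the requested rates
    cannot be placed at ``min_spacing``.
    """
    rng = np.random.default_rng(panel.seed if seed is None else seed)
    strains = panel.strain_names()
    probs = panel.carrier_probs()

    events: list[_Event] = []
    fam_names = sorted(ref.te_library)
    for sv_type in ("TE_insertion", "duplication", "insertion", "deletion", "inversion"):
        count = int(round(panel.sv_rates.get(sv_type, 0)))
        for _ in range(count):
            if sv_type == "TE_insertion":
                if not fam_names:
                    raise ValueError("TE insertions requested but the reference has no TE library")
                fam = fam_names[int(rng.integers(len(fam_names)))]
                seq = ref.te_library[fam]
                if panel.te_truncation > 0:
                    cut = int(len(seq) * rng.uniform(0, panel.te_truncation))
                    seq = seq[cut:] if rng.random() < 0.5 else seq[: len(seq) - cut]
                events.append(_Event("TE_insertion", len(seq), payload=seq, family=fam))
            elif sv_type == "insertion":
                lo, hi = panel.size_ranges["insertion"]
                ln = int(rng.integers(lo, hi + 1))
                events.append(_Event("insertion", ln, payload=random_seq(rng, ln)))
            else:
                lo, hi = panel.size_ranges[sv_type]
                ln = int(rng.integers(lo, hi + 1))
                spacer = panel.dup_spacer_length if sv_type == "duplication" else 0
                events.append(_Event(sv_type, ln, spacer=spacer))
    if panel.complex_mode:
        for _ in range(panel.n_complex_events):
            del_len = int(rng.integers(300, 2_001))
            ins_len = int(rng.integers(300, 2_001))
            events.append(
                _Event("substitution", del_len, payload=random_seq(rng, ins_len), ins_len=ins_len)
            )
    events = [events[i] for i in rng.permutation(len(events))]

    # --- placement: greedy capacity balancing across chromosomes, then random
    # gap layout per chromosome with >= min_spacing between consecutive events
    chrom_names = list(ref.chromosomes)
    te_zones = {c: [] for c in chrom_names}
    for chrom, s, e, _fam in ref.te_annotation:
        te_zones[chrom].append((s, e))
    capacity = {c: len(ref.chromosomes[c]) - 2 * EDGE_MARGIN for c in chrom_names}
    assigned: dict[str, list[_Event]] = {c: [] for c in chrom_names}
    for ev in events:
        need = ev.extent + panel.min_spacing
        best = max(chrom_names, key=lambda c: capacity[c])
        if capacity[best] < need:
            raise ValueError(
                f"spacing infeasible: cannot place event of extent {ev.extent} with "
                f"min_spacing={panel.min_spacing}"
            )
        capacity[best] -= need
        assigned[best].append(ev)

    for chrom in chrom_names:
        evs = assigned[chrom]
        if not evs:
            continue
        L = len(ref.chromosomes[chrom])
        zones = sorted(te_zones[chrom])
        total_extent = sum(e.extent for e in evs)
        zone_budget = sum(ze - zs + 2 * TE_ZONE_MARGIN for zs, ze in zones)
        free = (
            L - 2 * EDGE_MARGIN - total_extent - (len(evs) - 1) * panel.min_spacing - zone_budget
        )
        if free < 0:
            raise ValueError(f"spacing infeasible on {chrom}")
        gaps = rng.multinomial(free, np.full(len(evs) + 1, 1.0 / (len(evs) + 1)))
        pos = EDGE_MARGIN
        for i, ev in enumerate(evs):
            pos += int(gaps[i])
            # slide past any reference TE zone the footprint would touch
            moved = True
            while moved:
                moved = False
                for zs, ze in zones:
                    if pos - TE_ZONE_MARGIN < ze and zs < pos + ev.extent + TE_ZONE_MARGIN:
                        pos = ze + TE_ZONE_MARGIN
                        moved = True
            ev.start, ev.end = pos, pos + ev.extent
            pos += ev.extent + panel.min_spacing
        if pos - panel.min_spacing > L - EDGE_MARGIN:
            raise ValueError(f"spacing infeasible on {chrom}")
        for ev in evs:
            ev.chrom = chrom

    for ev in events:
        k = int(rng.choice(np.arange(1, panel.n_strains + 1), p=probs))
        ev.carriers = frozenset(
            strains[i] for i in rng.choice(panel.n_strains, size=k, replace=False)
        )

    # --- SNPs: uniform over positions clear of SV footprints and TE zones
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for ev in events:
        forbidden[ev.chrom].append((ev.start - SNP_MARGIN, ev.end + SNP_MARGIN))
    for chrom, zones in te_zones.items():
        forbidden[chrom] += [(s - SNP_MARGIN, e + SNP_MARGIN) for s, e in zones]
    for c in forbidden:
        forbidden[c].sort()

    def _draw_snp_positions(n: int) -> list[tuple[str, int]]:
        weights = np.array([len(ref.chromosomes[c]) for c in chrom_names], dtype=float)
        weights /= weights.sum()
        out: list[tuple[str, int]] = []
        used: set[tuple[str, int]] = set()
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 100 * n + 1000:
                raise ValueError("could not place requested SNPs outside SV footprints")
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            p = int(rng.integers(EDGE_MARGIN, len(ref.chromosomes[chrom]) - EDGE_MARGIN))
            if (chrom, p) in used:
                continue
            if any(a <= p < b for a, b in forbidden[chrom]):
                continue
            used.add((chrom, p))
            out.append((chrom, p))
        return out

    snp_events: list[tuple[str, int, str, str, frozenset]] = []  # chrom,pos,label,newbase,carriers
    spec = panel.snp_spec
    for label, n, alpha in (("syn", spec.n_syn, spec.syn_sfs_alpha),
                            ("nonsyn", spec.n_nonsyn, spec.nonsyn_sfs_alpha)):
        kvals = np.arange(1, panel.n_strains + 1, dtype=float)
        p = kvals ** (-alpha)
        p /= p.sum()
        for chrom, pos in _draw_snp_positions(n):
            old = ref.chromosomes[chrom][pos]
            new = "ACGT".replace(old, "")[int(rng.integers(3))]
            k = int(rng.choice(np.arange(1, panel.n_strains + 1), p=p))
            carriers = frozenset(strains[i] for i in rng.choice(panel.n_strains, size=k, replace=False))
            snp_events.append((chrom, pos, label, new, carriers))

    # --- truth table
    truth: list[TruthRecord] = []
    sv_counter = 0

    def _next_id() -> str:
        nonlocal sv_counter
        sv_counter += 1
        return f"SV{sv_counter:05d}"

    spacer_seqs: dict[int, str] = {}
    for i, ev in enumerate(sorted(events, key=lambda e: (e.chrom, e.start))):
        if ev.type == "substitution":
            truth.append(
                TruthRecord(_next_id(), "deletion", ev.chrom, ev.start, ev.end, ev.length, ev.carriers)
            )
            truth.append(
                TruthRecord(_next_id(), "insertion", ev.chrom, ev.start, ev.start, ev.ins_len, ev.carriers)
            )
            continue
        if ev.type == "duplication" and ev.spacer > 0:
            spacer_seqs[id(ev)] = random_seq(rng, ev.spacer)
        truth.append(
            TruthRecord(
                _next_id(),
                ev.type,
                ev.chrom,
                ev.start,
                ev.end,
                ev.length,
                ev.carriers,
                te_family=ev.family,
                spacer_length=ev.spacer,
            )
        )
    for chrom, pos, label, _new, carriers in sorted(snp_events, key=lambda t: (t[0], t[1])):
        truth.append(
            TruthRecord(_next_id(), "snp", chrom, pos, pos + 1, 1, carriers, snp_label=label)
        )

    # --- build strain genomes and TE annotations
    genomes: list[StrainGenome] = []
    te_annotations: dict[str, list[tuple[str, int, int, str]]] = {}
    events_by_chrom: dict[str, list[_Event]] = {c: [] for c in chrom_names}
    for ev in events:
        events_by_chrom[ev.chrom].append(ev)
    snps_by_chrom: dict[str, list[tuple[int, str, frozenset]]] = {c: [] for c in chrom_names}
    for chrom, pos, _label, new, carriers in snp_events:
        snps_by_chrom[chrom].append((pos, new, carriers))

    for strain in strains:
        chrom_seqs: dict[str, str] = {}
        te_rows: list[tuple[str, int, int, str]] = []
        for chrom in chrom_names:
            ref_seq = ref.chromosomes[chrom]
            edits: list[tuple[int, int, str, object]] = []
            for ev in events_by_chrom[chrom]:
                if strain in ev.carriers:
                    edits.append((ev.start, ev.end, ev.type, ev))
            for pos, new, carriers in snps_by_chrom[chrom]:
                if strain in carriers:
                    edits.append((pos, pos + 1, "snp", new))
            edits.sort(key=lambda e: e[0])

            parts: list[str] = []
            cur = 0
            out_pos = 0
            delta_points: list[tuple[int, int]] = []
            cum_delta = 0
            for start, end, kind, payload in edits:
                parts.append(ref_seq[cur:start])
                out_pos += start - cur
                cur = start
                if kind in ("insertion", "TE_insertion"):
                    seq = payload.payload
                    parts.append(seq)
                    if kind == "TE_insertion":
                        te_rows.append((chrom, out_pos, out_pos + len(seq), payload.family))
                    out_pos += len(seq)
                    cum_delta += len(seq)
                elif kind == "deletion":
                    cur = end
                    cum_delta -= end - start
                elif kind == "duplication":
                    seg = ref_seq[start:end]
                    spacer = spacer_seqs.get(id(payload), "")
                    parts.append(seg + spacer + seg)
                    out_pos += 2 * len(seg) + len(spacer)
                    cur = end
                    cum_delta += len(seg) + len(spacer)
                elif kind == "inversion":
                    parts.append(revcomp(ref_seq[start:end]))
                    out_pos += end - start
                    cur = end
                elif kind == "substitution":
                    parts.append(payload.payload)
                    out_pos += payload.ins_len
                    cur = end
                    cum_delta += payload.ins_len - (end - start)
                elif kind == "snp":
                    parts.append(payload)
                    out_pos += 1
                    cur = start + 1
                delta_points.append((start, cum_delta))
            parts.append(ref_seq[cur:])
            chrom_seqs[chrom] = "".join(parts)

            # pre-existing TE copies shifted into strain coordinates
            positions = [p for p, _d in delta_points]
            deltas = [d for _p, d in delta_points]
            for tchrom, s, e, fam in ref.te_annotation:
                if tchrom != chrom:
                    continue
                idx = np.searchsorted(positions, s, side="right") - 1
                d = deltas[idx] if idx >= 0 else 0
                te_rows.append((chrom, s + d, e + d, fam))
        te_rows.sort()
        genomes.append(StrainGenome(strain, chrom_seqs))
        te_annotations[strain] = te_rows

    truth_svs = [t for t in truth if t.type != "snp"]
    assert all(t.length > 0 for t in truth_svs)
    return genomes, te_annotations, truth


def make_candidate_set(
    genes: list[GeneModel],
    burdened_ids: set[str],
    target_n: int,
    enrichment_factor: float = 1.0,
    length_bias: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw a candidate gene set, optionally oversampling burdened/long genes.

    With ``enrichment_factor`` 1 and no length bias this is a uniform draw
    without replacement.  Burdened genes get relative weight
    ``enrichment_factor`` (infinite -> only burdened genes are eligible);
    with ``length_bias`` b > 1 gene weights gain a factor
    ``(length/median_length) ** (b - 1)``.
    """
    if target_n > len(genes):
        raise ValueError(f"target_n={target_n} exceeds {len(genes)} available genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = genes
    w = np.ones(len(pool), dtype=float)
    if not np.isfinite(enrichment_factor):
        pool = [g for g in genes if g.gene_id in burdened_ids]
        if target_n > len(pool):
            raise ValueError("infinite enrichment factor but too few burdened genes")
        w = np.ones(len(pool), dtype=float)
    else:
        w = np.array([enrichment_factor if g.gene_id in burdened_ids else 1.0 for g in pool])
    if length_bias is not None and length_bias != 1.0:
        lengths = np.array([g.length for g in pool], dtype=float)
        w = w * (lengths / np.median(lengths)) ** (length_bias - 1.0)
    idx = rng.choice(len(pool), size=target_n, replace=False, p=w / w.sum())
    return [pool[i].gene_id for i in sorted(idx)]
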
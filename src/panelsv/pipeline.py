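"""End-to-end orchestration: simulate -> align -> call -> merge -> sfs -> burden -> enrich.

All randomness derives from one top-level seed through per-stage seed
streams, so a fixed (config, seed) reproduces every output byte for byte and
single stages can be rerun in isolation.  Stages communicate through the
documented file interfaces under the output directory:

    ref.fasta genes.gff3 ref_te.bed truth.tsv strains/*.fasta te/*.bed te/*.out
    align/*.chains.tsv align/*.secondary.tsv calls/*.tsv calls/*.bed
    merged.tsv variants.vcf sfs.tsv sfs_chisq.tsv
    burden_records.tsv burden_bins.tsv burden_multiplicity.tsv
    candidates.tsv enrichment.yaml recovery.tsv manifest.json
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import align as al
from . import burden as bd
from . import detect as dt
from . import enrich as en
from . import io
from . import popsv as ps
from . import simulate as sim
from .burden import LengthBinning
from .models import SyntenicChain

log = logging.getLogger("panelsv")

STAGES = ["simulate", "align", "call", "merge", "sfs", "burden", "enrich"]


class AlignerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_anchor_len: int = 20
    max_seed_hits: int = 64
    max_multiplicity: int = 2
    max_join_gap: int = 10_000
    gap_penalty: float = 0.01
    min_chain_anchor_len: int = 40  # noise floor for chaining; anchors below go secondary


class CandidateSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    target_n: int = 31
    enrichment_factor: float = 3.0
    length_bias: float = 2.25


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: str = "results/pipeline"
    genome: sim.GenomeSpec = Field(default_factory=sim.GenomeSpec)
    panel: sim.PanelSpec = Field(default_factory=sim.PanelSpec)
    aligner: AlignerConfig = Field(default_factory=AlignerConfig)
    detector: dt.DetectorConfig = Field(default_factory=dt.DetectorConfig)
    bin_edges: list[int] = Field(default_factory=lambda: list(range(0, 50_001, 5_000)))
    reps: int = 100_000
    member_reps: int = 2_000
    exclude_complex: bool = True
    containment_overlap: bool = False
    grouped_loci: dict[str, list[str]] = Field(default_factory=dict)
    candidate: CandidateSpec = Field(default_factory=CandidateSpec)
    pos_tol: int = 100
    len_tol: float = 0.10


def load_config(path: str | None = None, **overrides) -> RunConfig:
    data = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage derived seed (stable, < 2^31)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)).generate_state(1)[0] & 0x7FFFFFFF)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig, outdir: Path):
    out = io.ensure_dir(outdir)
    seed = stage_seed(cfg.seed, "simulate")
    ref = sim.generate_reference(cfg.genome, seed=seed)
    genomes, te_annotations, truth = sim.plant_variants(ref, cfg.panel, seed=seed + 1)
    io.write_fasta(out / "ref.fasta", ref.chromosomes)
    io.write_gff3(out / "genes.gff3", ref.genes, {c: len(s) for c, s in ref.chromosomes.items()})
    io.write_bed(out / "ref_te.bed", ref.te_annotation)
    io.write_fasta(out / "te_library.fasta", ref.te_library)
    io.write_truth_tsv(out / "truth.tsv", truth)
    sdir = io.ensure_dir(out / "strains")
    tdir = io.ensure_dir(out / "te")
    for g in genomes:
        io.write_fasta(sdir / f"{g.strain_id}.fasta", g.chromosomes)
        rows = te_annotations[g.strain_id]
        io.write_bed(tdir / f"{g.strain_id}.bed", rows)
        io.write_rm_out(tdir / f"{g.strain_id}.out", rows)
    with open(out / "panel.yaml", "w") as fh:
        yaml.safe_dump(cfg.panel.model_dump(), fh, sort_keys=True)
    n_sv = sum(t.type != "snp" for t in truth)
    log.info("simulate: %d strains, %d SV loci, %d SNPs", len(genomes), n_sv, len(truth) - n_sv)
    return ref, genomes, te_annotations, truth


def _load_reference(outdir: Path):
    chroms = io.read_fasta(outdir / "ref.fasta")
    genes = io.read_gff3_genes(outdir / "genes.gff3")
    te_lib = io.read_fasta(outdir / "te_library.fasta") if (outdir / "te_library.fasta").exists() else {}
    te_ann = [
        (c, int(s), int(e), f) for c, s, e, f in io.read_bed(outdir / "ref_te.bed")
    ] if (outdir / "ref_te.bed").exists() else []
    return sim.ReferencePackage(chroms, genes, te_lib, te_ann)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{path} missing; run the '{producer}' stage first")
    return path


def _strain_names(outdir: Path) -> list[str]:
    sdir = _require(outdir / "strains", "simulate")
    return sorted(p.stem for p in sdir.glob("*.fasta"))


def stage_align(cfg: RunConfig, outdir: Path):
    out = Path(outdir)
    ref = _load_reference(out)
    adir = io.ensure_dir(out / "align")
    a = cfg.aligner
    indexes = {
        c: al.AnchorIndex(seq, a.min_anchor_len, c) for c, seq in ref.chromosomes.items()
    }
    chains_by_strain: dict[str, list[SyntenicChain]] = {}
    for strain in _strain_names(out):
        qry = io.read_fasta(out / "strains" / f"{strain}.fasta")
        chains: list[SyntenicChain] = []
        secondary = []
        for chrom in sorted(ref.chromosomes):
            if chrom not in qry:
                continue
            anchors = indexes[chrom].anchors(qry[chrom], chrom, a.max_seed_hits)
            ch, sec = al.chain_anchors(
                anchors,
                gap_penalty=a.gap_penalty,
                max_join_gap=a.max_join_gap,
                max_multiplicity=a.max_multiplicity,
                min_anchor_len=a.min_chain_anchor_len,
            )
            chains.extend(ch)
            secondary.extend(sec)
        blocks = [b for ch in chains for b in ch.blocks]
        io.write_coords_tsv(adir / f"{strain}.chains.tsv", blocks)
        io.write_coords_tsv(
            adir / f"{strain}.secondary.tsv",
            [al.AlignmentBlock(s.ref_chrom, s.ref_start, s.ref_end, s.qry_seq,
                               s.qry_start, s.qry_end, s.strand) for s in secondary],
        )
        chains_by_strain[strain] = chains
        log.info("align %s: %d blocks, %d secondary anchors", strain, len(blocks), len(secondary))
    return chains_by_strain


def _blocks_to_chains(blocks) -> list[SyntenicChain]:
    by_pair: dict[tuple[str, str], list] = {}
    for b in blocks:
        by_pair.setdefault((b.ref_chrom, b.qry_seq), []).append(b)
    chains = []
    for (rc, qn), bl in sorted(by_pair.items()):
        bl.sort(key=lambda b: (b.ref_start, b.qry_start))
        chains.append(SyntenicChain(rc, qn, bl))
    return chains


def stage_call(cfg: RunConfig, outdir: Path, alignment_files: dict[str, str] | None = None,
               dialect: str = "coords"):
    out = Path(outdir)
    ref = _load_reference(out)
    cdir = io.ensure_dir(out / "calls")
    per_strain = {}
    for strain in _strain_names(out):
        if alignment_files is not None:
            blocks = io.read_alignments(alignment_files[strain], dialect, set(ref.chromosomes))
        else:
            blocks = io.read_coords_tsv(
                _require(out / "align" / f"{strain}.chains.tsv", "align"), set(ref.chromosomes)
            )
        chains = _blocks_to_chains(blocks)
        qry = io.read_fasta(out / "strains" / f"{strain}.fasta")
        calls = dt.classify_svs(chains, ref, qry, cfg.detector, strain_id=strain)
        te_rows = [
            (c, int(s), int(e), f) for c, s, e, f in io.read_bed(out / "te" / f"{strain}.bed")
        ]
        calls = dt.annotate_te_insertions(calls, te_rows, cfg.detector.te_overlap_frac, set(qry))
        calls = dt.flag_complex(calls, cfg.detector)
        io.write_calls_tsv(cdir / f"{strain}.tsv", calls)
        io.write_bed(
            cdir / f"{strain}.bed",
            [(c.ref_chrom, c.ref_start, c.ref_end, c.type) for c in calls],
        )
        per_strain[strain] = calls
        log.info("call %s: %d calls", strain, len(calls))
    return per_strain


def stage_merge(cfg: RunConfig, outdir: Path):
    out = Path(outdir)
    strains = _strain_names(out)
    per_strain = {
        s: io.read_calls_tsv(_require(out / "calls" / f"{s}.tsv", "call")) for s in strains
    }
    if not any(per_strain.values()):
        log.warning("merge: no calls found; writing header-only outputs")
    merged = ps.merge_calls(per_strain)
    io.write_merged_tsv(out / "merged.tsv", merged)
    io.write_bed(
        out / "merged.bed",
        [(m.ref_chrom, m.ref_start, m.ref_end, f"{m.sv_id}:{m.type}") for m in merged],
    )
    ref_seqs = io.read_fasta(out / "ref.fasta")
    ps.write_vcf(merged, strains, ref_seqs, out / "variants.vcf")
    log.info("merge: %d calls -> %d merged variants", sum(map(len, per_strain.values())), len(merged))
    return merged


def stage_sfs(cfg: RunConfig, outdir: Path):
    out = Path(outdir)
    merged = io.read_merged_tsv(_require(out / "merged.tsv", "merge"))
    truth = io.read_truth_tsv(_require(out / "truth.tsv", "simulate"))
    N = cfg.panel.n_strains
    spectra = {
        "TE_insertion": ps.folded_sfs(
            [m for m in merged if m.type == "TE_insertion"], N, cfg.exclude_complex
        ),
        "duplication": ps.folded_sfs(
            [m for m in merged if m.type == "duplication"], N, cfg.exclude_complex
        ),
        "nonsyn_snp": ps.truth_folded_sfs(truth, N, types=("snp",), snp_label="nonsyn"),
        "syn_snp": ps.truth_folded_sfs(truth, N, types=("snp",), snp_label="syn"),
    }
    rows = [
        dict(category=cat, frequency_class=i, count=n)
        for cat, sfs in spectra.items()
        for i, n in sorted(sfs.counts.items())
    ]
    pd.DataFrame(rows, columns=["category", "frequency_class", "count"]).to_csv(
        out / "sfs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            dict(sv_id=m.sv_id, type=m.type, x=m.allele_count,
                 y_class=min(m.allele_count, N - m.allele_count), ce_flag=m.ce_flag)
            for m in merged
        ],
        columns=["sv_id", "type", "x", "y_class", "ce_flag"],
    ).to_csv(out / "frequencies.tsv", sep="\t", index=False)
    comparisons = [
        ("TE_insertion", "nonsyn_snp"),
        ("duplication", "nonsyn_snp"),
        ("TE_insertion", "duplication"),
        ("nonsyn_snp", "syn_snp"),
    ]
    crows = []
    for a, b in comparisons:
        for scheme in ("full", "singleton"):
            try:
                stat, df_, p = ps.sfs_chisq(spectra[a], spectra[b], scheme)
            except ValueError:
                stat, df_, p = float("nan"), 0, float("nan")
            crows.append(dict(a=a, b=b, scheme=scheme, statistic=stat, df=df_, p=p))
    pd.DataFrame(crows).to_csv(out / "sfs_chisq.tsv", sep="\t", index=False)
    log.info("sfs: %s", {k: v.total() for k, v in spectra.items()})
    return spectra


def stage_burden(cfg: RunConfig, outdir: Path):
    out = Path(outdir)
    merged = io.read_merged_tsv(_require(out / "merged.tsv", "merge"))
    ref = _load_reference(out)
    founders = _strain_names(out)
    per_strain = bd.gene_sv_overlap(
        merged, ref.genes, containment=cfg.containment_overlap,
        chrom_names=set(ref.chromosomes),
    )
    records = bd.diploid_burden(per_strain, ref.genes, founders)
    bins = LengthBinning(cfg.bin_edges)
    summary, mult = bd.burden_by_length(records, ref.genes, bins)
    pd.DataFrame(records).to_csv(out / "burden_records.tsv", sep="\t", index=False)
    summary.to_csv(out / "burden_bins.tsv", sep="\t")
    mult.to_csv(out / "burden_multiplicity.tsv", sep="\t", index=False)
    frac = sum(r.multiplicity >= 1 for r in records) / len(records) if records else 0.0
    log.info("burden: %d pairs, %.1f%% gene x pair combinations burdened",
             len(founders) * (len(founders) - 1) // 2, 100 * frac)
    return records, summary


def stage_enrich(cfg: RunConfig, outdir: Path):
    out = Path(outdir)
    merged = io.read_merged_tsv(_require(out / "merged.tsv", "merge"))
    ref = _load_reference(out)
    genes = ref.genes
    for gid, group in cfg.grouped_loci.items():
        genes = en.collapse_grouped_locus(genes, group, gid)
    per_strain = bd.gene_sv_overlap(merged, genes, chrom_names=set(ref.chromosomes))
    gene_svs: dict[str, set[str]] = {}
    for gmap in per_strain.values():
        for gid, svs in gmap.items():
            gene_svs.setdefault(gid, set()).update(svs)
    burdened = set(gene_svs)
    cand_seed = stage_seed(cfg.seed, "enrich")
    candidates = sim.make_candidate_set(
        genes, burdened, cfg.candidate.target_n,
        cfg.candidate.enrichment_factor, cfg.candidate.length_bias, seed=cand_seed,
    )
    result = en.run_enrichment(
        genes, burdened, candidates,
        {g: len(s) for g, s in gene_svs.items()},
        bins=LengthBinning(cfg.bin_edges), reps=cfg.reps,
        member_reps=cfg.member_reps, seed=cand_seed + 1,
    )
    by_id = {g.gene_id: g for g in genes}
    pd.DataFrame(
        [
            dict(gene_id=g, length=by_id[g].length, burdened=int(g in burdened),
                 n_svs=len(gene_svs.get(g, ())))
            for g in candidates
        ]
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    report = dict(
        observed_burdened_candidates=result.observed,
        n_candidates=result.n_candidates,
        table=[[int(x) for x in row] for row in result.table],
        fisher_p=result.fisher_p,
        mc_expected_mean=result.mc_expected_mean,
        mc_p=result.mc_p,
        reps=result.reps,
        seed=result.seed,
        candidate_density=list(result.candidate_density),
        genome_density=list(result.genome_density),
        mc_expected_density=list(result.mc_expected_density),
        length_means=list(result.length_means),
        length_p=result.length_p,
        length_match_pass_fraction=result.length_match_pass_fraction,
        bin_edges=cfg.bin_edges,
    )
    with open(out / "enrichment.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    log.info("enrich: observed %d/%d burdened, mc_p=%.4g fisher_p=%.4g",
             result.observed, result.n_candidates, result.mc_p, result.fisher_p)
    return result


def stage_recovery(cfg: RunConfig, outdir: Path):
    """Score merged/per-strain calls against the planted truth table."""
    out = Path(outdir)
    truth = io.read_truth_tsv(_require(out / "truth.tsv", "simulate"))
    calls = [
        c for s in _strain_names(out)
        for c in io.read_calls_tsv(_require(out / "calls" / f"{s}.tsv", "call"))
    ]
    table = dt.score_recovery(calls, truth, cfg.pos_tol, cfg.len_tol)
    table.to_csv(out / "recovery.tsv", sep="\t")
    return table


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage; write a manifest recording seed, config hash and outputs."""
    out = io.ensure_dir(outdir or cfg.outdir)
    manifest = dict(
        seed=cfg.seed,
        config_hash=config_hash(cfg),
        config=json.loads(cfg.model_dump_json()),
        stages={},
        status="running",
    )
    stage_outputs = {
        "simulate": ["ref.fasta", "genes.gff3", "truth.tsv", "strains", "te"],
        "align": ["align"],
        "call": ["calls"],
        "merge": ["merged.tsv", "variants.vcf"],
        "sfs": ["sfs.tsv", "sfs_chisq.tsv"],
        "burden": ["burden_records.tsv", "burden_bins.tsv", "burden_multiplicity.tsv"],
        "enrich": ["candidates.tsv", "enrichment.yaml"],
    }
    funcs = dict(
        simulate=stage_simulate, align=stage_align, call=stage_call,
        merge=stage_merge, sfs=stage_sfs, burden=stage_burden, enrich=stage_enrich,
    )
    try:
        for name in STAGES:
            funcs[name](cfg, out)
            manifest["stages"][name] = dict(status="ok", outputs=stage_outputs[name])
        stage_recovery(cfg, out)
        manifest["stages"]["recovery"] = dict(status="ok", outputs=["recovery.tsv"])
        manifest["status"] = "ok"
    except Exception as err:
        manifest["status"] = f"failed: {err}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
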
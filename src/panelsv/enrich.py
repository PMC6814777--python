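"""Candidate-gene SV enrichment testing.

The burden contrast (candidate vs rest of genome, SV-burdened vs SV-free) is
tested two ways: a two-sided Fisher's exact test on the 2x2 counts, and a
length-matched Monte Carlo null built by drawing, from each gene-length bin,
a burdened count from the hypergeometric distribution with that bin's
genome margins and the candidate set's bin occupancy.  Because candidate
genes tend to be long and long genes are more often burdened, the
length-matched null is the fair comparison; the Fisher test ignores length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .burden import LengthBinning
from .models import GeneModel


def fisher_burden_test(
    cand_burdened: int, cand_free: int, rest_burdened: int, rest_free: int
) -> tuple[np.ndarray, float]:
    """Two-sided Fisher's exact test on the candidate/rest burden table.

    Two-sidedness follows the point-probability rule: the p-value sums the
    probabilities of all tables (margins fixed) no more probable than the
    observed one, ties included.
    """
    table = np.array([[cand_burdened, cand_free], [rest_burdened, rest_free]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


@dataclass
class MCResult:
    null_counts: np.ndarray
    expected_mean: float
    mc_p: float
    observed: int
    reps: int
    seed: int | None
    bin_table: pd.DataFrame  # per-bin n (candidates), K, N
    replicate_lengths: list[np.ndarray] | None = None
    replicate_sv_counts: np.ndarray | None = None


def mc_length_matched(
    candidate_lengths: list[int],
    genes: list[GeneModel],
    burdened_ids: set[str],
    observed: int,
    bins: LengthBinning | None = None,
    reps: int = 100_000,
    seed: int | None = None,
    plus_one: bool = False,
    sample_members: bool = False,
    gene_sv_counts: dict[str, int] | None = None,
) -> MCResult:
    """Length-matched Monte Carlo null for the burdened-candidate count.

    Each replicate draws, for every length bin, a burdened count from
    Hypergeometric(N_bin, K_bin, n_bin) — n from the candidates, K/N from
    the genome — and sums across bins.  ``mc_p`` is the upper-tail fraction
    of replicates >= ``observed`` (``plus_one`` switches to the
    (k+1)/(reps+1) variant).  With ``sample_members`` the replicates draw
    actual gene identities so member lengths and SV counts are available
    for length-match validation and density statistics.
    """
    bins = bins or LengthBinning()
    part = bins.partition(genes, burdened_ids)
    labels = bins.labels()
    n_bin = np.zeros(bins.n_bins, dtype=int)
    for ln in candidate_lengths:
        n_bin[bins.bin_index(ln)] += 1
    N_bin = part["N"].to_numpy()
    K_bin = part["K"].to_numpy()
    for i, lab in enumerate(labels):
        if n_bin[i] > N_bin[i]:
            raise ValueError(
                f"bin {lab}: {n_bin[i]} candidates but only {N_bin[i]} genome genes"
            )
    rng = np.random.default_rng(seed)
    totals = np.zeros(reps, dtype=np.int64)
    replicate_lengths = None
    replicate_sv_counts = None
    if not sample_members:
        for i in range(bins.n_bins):
            if n_bin[i] > 0:
                totals += rng.hypergeometric(K_bin[i], N_bin[i] - K_bin[i], n_bin[i], size=reps)
    else:
        by_bin: dict[int, list[GeneModel]] = {i: [] for i in range(bins.n_bins)}
        for g in genes:
            by_bin[bins.bin_index(g.length)].append(g)
        replicate_lengths = [np.empty(0)] * reps
        lens_acc: list[list[np.ndarray]] = [[] for _ in range(reps)]
        sv_acc = np.zeros(reps, dtype=np.int64)
        for i in range(bins.n_bins):
            if n_bin[i] == 0:
                continue
            pool = by_bin[i]
            lengths = np.array([g.length for g in pool])
            burdened = np.array([g.gene_id in burdened_ids for g in pool])
            svs = (
                np.array([gene_sv_counts.get(g.gene_id, 0) for g in pool])
                if gene_sv_counts is not None
                else np.zeros(len(pool), dtype=int)
            )
            keys = rng.random((reps, len(pool)))
            picks = np.argpartition(keys, n_bin[i] - 1, axis=1)[:, : n_bin[i]]
            totals += burdened[picks].sum(axis=1)
            sv_acc += svs[picks].sum(axis=1)
            for r in range(reps):
                lens_acc[r].append(lengths[picks[r]])
        replicate_lengths = [np.concatenate(x) if x else np.empty(0) for x in lens_acc]
        replicate_sv_counts = sv_acc
    if plus_one:
        mc_p = (int((totals >= observed).sum()) + 1) / (reps + 1)
    else:
        mc_p = int((totals >= observed).sum()) / reps
    bin_table = pd.DataFrame({"bin": labels, "n": n_bin, "K": K_bin, "N": N_bin}).set_index("bin")
    return MCResult(
        null_counts=totals,
        expected_mean=float(totals.mean()),
        mc_p=float(mc_p),
        observed=observed,
        reps=reps,
        seed=seed,
        bin_table=bin_table,
        replicate_lengths=replicate_lengths,
        replicate_sv_counts=replicate_sv_counts,
    )


def validate_length_match(
    replicate_lengths: list[np.ndarray],
    candidate_lengths: list[int],
    threshold: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Fraction of replicates whose lengths are rank-indistinguishable from
    the candidates (two-sided Mann-Whitney p > threshold)."""
    ps = np.array(
        [
            stats.mannwhitneyu(lens, candidate_lengths, alternative="two-sided").pvalue
            if len(lens)
            else np.nan
            for lens in replicate_lengths
        ]
    )
    return float(np.mean(ps > threshold)), ps


def density_stats(
    gene_lengths: list[int], n_burdened_genes: int, n_svs: int
) -> tuple[float, float]:
    """(burdened genes per Mbp of gene spans, SVs per Mbp of gene spans)."""
    span = sum(gene_lengths)
    if span <= 0:
        raise ValueError("zero total gene span")
    mbp = span / 1e6
    return n_burdened_genes / mbp, n_svs / mbp


def length_comparison(
    candidate_lengths: list[int], other_lengths: list[int]
) -> tuple[float, float, float]:
    """Group means and two-sided rank-sum p (exact for combined n <= 30)."""
    if not candidate_lengths or not other_lengths:
        raise ValueError("empty length list")
    method = "exact" if len(candidate_lengths) + len(other_lengths) <= 30 else "asymptotic"
    res = stats.mannwhitneyu(
        candidate_lengths, other_lengths, alternative="two-sided", method=method
    )
    return (
        float(np.mean(candidate_lengths)),
        float(np.mean(other_lengths)),
        float(res.pvalue),
    )


def select_candidates(
    gene_table: pd.DataFrame,
    euchromatin_bounds: dict[str, tuple[int, int]],
) -> tuple[list[str], dict[str, int]]:
    """Apply the candidate filters and euchromatin bounds.

    ``gene_table`` needs columns gene_id, chrom, start, end, in_qtl_peak,
    functional_evidence, evidence_sv_independent.  Returns the retained ids
    and the number removed by each filter (applied in order).
    """
    removed = {"qtl_peak": 0, "functional_evidence": 0, "sv_knowledge": 0, "bounds": 0}
    kept = []
    for r in gene_table.itertuples(index=False):
        if not r.in_qtl_peak:
            removed["qtl_peak"] += 1
            continue
        if not r.functional_evidence:
            removed["functional_evidence"] += 1
            continue
        if not r.evidence_sv_independent:
            removed["sv_knowledge"] += 1
            continue
        lo, hi = euchromatin_bounds.get(r.chrom, (None, None))
        if lo is None or r.start < lo or r.end > hi:
            removed["bounds"] += 1
            continue
        kept.append(r.gene_id)
    return kept, removed


def collapse_grouped_locus(
    genes: list[GeneModel], group: list[str], group_id: str
) -> list[GeneModel]:
    """Collapse a named gene set (e.g. a tandem array) into one locus spanning
    the group's extent, for sensitivity analyses."""
    members = [g for g in genes if g.gene_id in group]
    if not members:
        return list(genes)
    chroms = {g.chrom for g in members}
    if len(chroms) != 1:
        raise ValueError("grouped locus spans multiple chromosomes")
    merged = GeneModel(
        group_id, members[0].chrom, min(g.start for g in members), max(g.end for g in members)
    )
    rest = [g for g in genes if g.gene_id not in group]
    return sorted(rest + [merged], key=lambda g: (g.chrom, g.start))


@dataclass
class EnrichmentResult:
    observed: int
    n_candidates: int
    table: np.ndarray
    fisher_p: float
    mc_expected_mean: float
    mc_p: float
    reps: int
    seed: int | None
    candidate_density: tuple[float, float]
    genome_density: tuple[float, float]
    mc_expected_density: tuple[float, float]
    length_means: tuple[float, float]
    length_p: float
    length_match_pass_fraction: float
    extras: dict = field(default_factory=dict)


def run_enrichment(
    genes: list[GeneModel],
    burdened_ids: set[str],
    candidate_ids: list[str],
    gene_sv_counts: dict[str, int],
    bins: LengthBinning | None = None,
    reps: int = 100_000,
    member_reps: int = 2_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Full enrichment analysis of one candidate set against the genome."""
    bins = bins or LengthBinning()
    by_id = {g.gene_id: g for g in genes}
    cand = [by_id[g] for g in candidate_ids]
    rest = [g for g in genes if g.gene_id not in set(candidate_ids)]
    observed = sum(g.gene_id in burdened_ids for g in cand)
    rest_burdened = sum(g.gene_id in burdened_ids for g in rest)
    table, fisher_p = fisher_burden_test(
        observed, len(cand) - observed, rest_burdened, len(rest) - rest_burdened
    )
    cand_lengths = [g.length for g in cand]
    mc = mc_length_matched(
        cand_lengths, genes, burdened_ids, observed, bins=bins, reps=reps, seed=seed
    )
    mcm = mc_length_matched(
        cand_lengths,
        genes,
        burdened_ids,
        observed,
        bins=bins,
        reps=member_reps,
        seed=None if seed is None else seed + 1,
        sample_members=True,
        gene_sv_counts=gene_sv_counts,
    )
    pass_frac, _ = validate_length_match(mcm.replicate_lengths, cand_lengths)
    cand_svs = sum(gene_sv_counts.get(g, 0) for g in candidate_ids)
    rest_svs = sum(gene_sv_counts.get(g.gene_id, 0) for g in rest)
    cand_density = density_stats(cand_lengths, observed, cand_svs)
    genome_density = density_stats([g.length for g in rest], rest_burdened, rest_svs)
    mean_rep_span = float(np.mean([lens.sum() for lens in mcm.replicate_lengths])) / 1e6
    mc_density = (
        float(mcm.null_counts.mean()) / mean_rep_span,
        float(mcm.replicate_sv_counts.mean()) / mean_rep_span,
    )
    mean_c, mean_r, length_p = length_comparison(cand_lengths, [g.length for g in rest])
    return EnrichmentResult(
        observed=observed,
        n_candidates=len(cand),
        table=table,
        fisher_p=fisher_p,
        mc_expected_mean=mc.expected_mean,
        mc_p=mc.mc_p,
        reps=reps,
        seed=seed,
        candidate_density=cand_density,
        genome_density=genome_density,
        mc_expected_density=mc_density,
        length_means=(mean_c, mean_r),
        length_p=length_p,
        length_match_pass_fraction=pass_frac,
        extras=dict(bin_table=mc.bin_table),
    )
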
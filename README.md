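# panelsv

Assembly-based structural-variant (SV) analysis on a panel of strain genomes:
SV discovery from pairwise whole-genome alignment, population merging with a
folded site-frequency spectrum, per-gene SV burden in all synthetic diploids,
and length-matched candidate-gene enrichment testing — all exercised end to
end on a fully synthetic founder panel with known ground truth.

## The problem

High-quality de novo assemblies make large (>100 bp) structural variants —
TE insertions, duplication CNVs, indels, inversions — directly visible by
aligning each strain assembly to a reference, where short-read genotyping
misses a large fraction of them. Given a panel of N haploid founder strains,
three population questions follow:

1. **How rare are SVs?** For each merged variant with allele count *x* the
   folded spectrum uses the minor-allele count *y = min(x, N − x)*; spectra of
   SV classes are compared with synonymous/nonsynonymous SNP classes by
   Pearson χ² over frequency classes (all classes, or singleton vs rest).
2. **How burdened are genes?** Every pair of founders forms one synthetic
   diploid (C(13,2) = 78 pairings); a gene's *multiplicity* in a diploid is
   the number of unique SVs whose footprint intersects the gene span across
   the two haplotypes, and a gene with multiplicity ≥ 1 is *SV-burdened*.
3. **Are candidate genes enriched for SVs?** Besides Fisher's exact test on
   the 2×2 burdened/free × candidate/rest table, a length-matched null draws,
   per gene-length bin, a burdened count from
   Hypergeometric(N_bin, K_bin, n_bin) and sums over bins (100,000
   replicates), because long genes are both more often burdened and more
   often nominated as candidates.

Because the real panel's assemblies are not required here, a first-class
synthetic-data generator builds the study conditions: a ~5 Mb reference with
genes and an embedded TE library, 13 derived strains with ~300 planted SV
loci (rare-skewed carrier counts) plus labeled SNPs, and a truth table that
the caller is scored against. On this default panel the pipeline recovers
every planted SV type with precision = recall = 1.0 and reproduces the
truth-derived folded SFS exactly.

## Worked example

Run the numbered drivers in order (from `analysis/`), or equivalently
`panelsv run-all --seed 1 --outdir results/study`:

```bash
cd analysis
python 01_simulate.py --seed 1 --outdir ../results/study
python 03_call_svs.py --seed 1 --outdir ../results/study   # after 02_align.py
```

which prints, after alignment and calling:

```
561 calls across 13 strains; CE flags: 0=561 1=0 2=0
              n_calls  n_truth  matched_calls  matched_truth  precision  recall
TE_insertion      348      348            348            348      1.000   1.000
deletion           93       93             93             93      1.000   1.000
duplication        44       44             44             44      1.000   1.000
insertion          73       73             73             73      1.000   1.000
inversion           3        3              3              3      1.000   1.000
overall           561      561            561            561      1.000   1.000
```

Every one of the 561 per-strain calls (300 distinct loci across carriers)
matches a planted truth record of the same type within 100 bp and 10% length
tolerance, with no false calls. The later steps report the population
analyses, e.g. `04_merge_sfs.py`:

```
300 merged variants (197 singletons)
TE_insertion   n= 170 singleton fraction 0.61
nonsyn_snp     n= 990 singleton fraction 0.53
syn_snp        n= 973 singleton fraction 0.36
```

(nonsynonymous-like SNPs are planted rarer than synonymous-like ones; the
χ² comparison of those two spectra gives p ≈ 5e-12) and `06_enrichment.py`:

```
candidates: 26/31 burdened (83.9%); Fisher p = 1.32e-09
length-matched MC: expected 21.8, observed 26 (+19%), mc_p = 0.0206 over 100,000 replicates
length match validated: 100.0% of member replicates have MWU p > 0.1 vs candidate lengths
candidate vs genome mean length: 16.0 kb vs 4.4 kb (rank-sum p = 9.4e-13)
```

showing why the length-matched null matters: the candidate draw is biased
toward long genes, so the naive Fisher p-value vastly overstates the
enrichment that remains once length is controlled.

## Layout

- `src/panelsv/` — library: `simulate` (synthetic panel + truth),
  `align` (MEM anchoring, chaining, reference scaffolding), `detect`
  (junction-arithmetic SV classification, TE annotation, CE flags,
  recovery scoring), `popsv` (merge, VCF, folded SFS, χ², concordance),
  `burden` (diploid burden, length bins), `enrich` (Fisher, length-matched
  MC, densities, rank tests), `pipeline` + `cli` (orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model, parameter defaults, and design rationale.
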
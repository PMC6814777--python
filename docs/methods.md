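# Methods

## Synthetic panel: what is emulated, and what is not

The generator (`panelsv.simulate`) builds the study conditions directly
rather than resimulating sequencing or assembly:

- **Reference** — five chromosomes of 1 Mb each (desk-scale stand-in for the
  ~94.5 Mb of euchromatin on five chromosome arms), uniform-random sequence,
  with one copy of each of 8 TE families (500–5000 bp, random sequence)
  embedded and annotated. 600 genes are packed left-to-right with random
  gaps; lengths are lognormal (median 3.3 kb, σ = 1, hence mean ≈ 5.4 kb,
  the genome-wide average gene size the analysis is anchored to). The
  lognormal family is our choice: the study states only the means, and gene
  lengths are heavy-tailed right-skewed in every annotated genome.
- **Panel** — 13 haploid strains derived from the reference by planting
  ~300 distinct SV loci: 170 TE insertions, 27 tandem duplications, 50
  insertions, 51 deletions, 2 inversions. The type mix keeps the real
  panel's proportions (TE insertions dominate, inversions are ~0.5%); the
  total is scaled to the 5 Mb genome so that events can be spaced ≥ 10 kb
  apart. Each locus gets a carrier count k drawn from a rare-skewed
  distribution P(k) ∝ k^(−α) over 1..13 (α = 2 for SVs; SNPs use α = 1.5
  for nonsynonymous-like and α = 1.0 for synonymous-like labels, so the
  expected ordering SV ≺ nsSNP ≺ sSNP in minor-allele frequency holds by
  construction). 2,000 labeled point variants are planted outside SV
  footprints and TE spans.
- **Event geometry** — insertions/deletions 150–2000 bp, duplications
  300–3000 bp (two tandem copies; an optional spacer between the copies is
  off by default), inversions 500–5000 bp, TE insertions full library
  copies (optional end-truncation is off by default). Events avoid
  chromosome ends (2 kb) and reference TE copies (500 bp).
- **Complex mode** (off by default) additionally plants substitution-like
  events (delete 300–2000 bp, insert a different 300–2000 bp) to exercise
  the CE flags.

What the generator deliberately does **not** model: heterochromatin,
codon-aware SNP effects (syn/nonsyn are opaque labels), linkage and
recombination structure, nested/overlapping variation in default mode,
sequencing or assembly error. Passing tests therefore demonstrate the
correctness of the calling/merging/burden/enrichment machinery under clean,
well-spaced variation — not robustness to assembly artifacts or repeats
beyond the planted TE library.

## Alignment

`find_anchors` enumerates **all maximal exact matches** ≥ `min_len`
(default 20 bp) on both strands using exact 2-bit packed k-mer seeds
(k = min(min_len, 32)) grouped into diagonal runs; a run of consecutive
seed hits on one diagonal is exactly one maximal match, so the enumeration
is exact, not heuristic (verified against an O(n²) scan in the tests).

Chaining picks the best reference- and query-monotone subset, maximizing
total anchored length minus a linear gap penalty (0.01/bp, gaps capped at
`max_join_gap` = 10 kb). Three deliberate choices:

- **Repeat handling**: instead of external repeat masking, anchors whose
  reference interval is hit by more than `max_multiplicity` (= 2) anchors
  are dropped before chaining; dropped/unchained anchors are retained as
  "secondary" so duplicated sequence stays visible.
- **Inversions**: minus-strand anchors are first grouped into locally
  collinear units (reference ascending, query descending — the collinear
  order inside an inverted segment), and each unit enters the main chain
  as one block. Without this, a point mismatch inside an inversion would
  split it into blocks that cannot both be query-monotone.
- **Jitter slack**: consecutive blocks may overlap by ≤ 50 bp in the query
  (chance extension of anchor ends); overlaps are trimmed after traceback.
  Reference overlap between consecutive blocks is allowed up to
  `max_join_gap` — that overlap *is* the tandem-duplication signal.
  Anchors shorter than 40 bp are excluded from chaining in the pipeline
  (noise floor; they remain available as secondaries).

Reference-based scaffolding assigns contigs to chromosomes by mutual-best
anchored length (ties: lexicographically smaller chromosome name), orients
by majority strand, joins placed contigs with exactly 100 N characters and
prefixes unplaced sequence names with "U".

## SV classification

For each junction between adjacent chain blocks, with reference gap r and
query gap q (bp):

| signature | call |
|---|---|
| q − r > L | insertion of q − r at the junction point |
| r − q > L | deletion of the reference gap |
| r < −L | tandem duplication of the overlap, emitted as an insertion-record CNV (copy number 2) |
| r > L and q > L | substitution-like: resolved by gap inspection, see below |
| strand run opposite to flanks | inversion over the run's reference extent |

with L = `min_sv_len` = 100 bp, so every emitted call is > 100 bp and
SNP-scale junctions emit nothing. Substitution-like junctions (both r and
q large) are resolved in three steps: equal-length gaps with ≥ 95% identity
are unanchored repeats (no event — this happens whenever a TE family has
enough copies in one strain that the multiplicity cap drops every anchor
over its reference copy); otherwise the two gap sequences are re-anchored
*against each other* — with no multiplicity cap, since a repeat is usually
unique within one junction — and the local chain is spliced in and
classified recursively, which recovers, for example, a small deletion
sitting next to a multiplicity-dropped TE copy. Only a junction whose gap
sequences share no local anchors at all is a true substitution: both the
deletion and the insertion are emitted and flagged complex.

Insertions whose query interval contains ≥ 90% of a TE annotation are
retyped TE insertions (all qualifying families listed). CE flags: 2 for
complex junctions, 1 for calls within 5 kb of a CE = 2 footprint, 0
otherwise. Recovery scoring matches calls to per-carrier truth records of
the same strain/type/chromosome greedily by breakpoint distance, within
100 bp and 10% length.

## Population merging and SFS

Same-type calls with overlapping or book-ended reference footprints are
transitively merged (insertion points padded ±100 bp for clustering only);
allele count x = number of distinct carrier strains. The folded SFS bins
variants by y = min(x, N − x), dropping fixed variants and (by default)
CE ≥ 1 variants. χ² comparisons use the 2×C category × frequency-class
table without continuity correction, either over all folded classes present
or collapsed to singleton/non-singleton. We report the degrees of freedom
of the table actually tested (classes − 1); the full folded table has at
most ⌊N/2⌋ classes, so a nominal "N − 1 df" cannot apply to folded data and
is not replicated. Variants are polarized against the reference (reference
alleles are not counted in x); folding makes this immaterial up to class
relabeling.

## Diploid burden

All C(13,2) = 78 founder pairs are enumerated; a gene's multiplicity in a
pair is the size of the union of variant ids overlapping its span across
the two haplotypes (shared variants count once). "Falls within the gene
span" is read as any ≥ 1 bp footprint overlap — a deletion larger than the
gene still affects it — with a containment-only mode available; insertion
breakpoints must lie strictly inside the span (a breakpoint at either
boundary inserts outside the transcribed interval under half-open
coordinates). Complex variants are *included* in burden: they are real
mutations, and only the SFS analysis excludes them. Length bins default to
5-kb steps with [50 kb, ∞) on top.

## Enrichment

Fisher's exact test (two-sided, point-probability rule) on the 2×2 table
ignores gene length; the length-matched Monte Carlo null is the fair test.
Each of 100,000 replicates draws per-bin burdened counts from
Hypergeometric(N_bin, K_bin, n_bin) and sums; `mc_p` is the plain upper-tail
fraction (#replicates ≥ observed)/reps, matching how such tail percentages
are usually quoted, with a (k+1)/(reps+1) variant behind a flag. A
member-sampling mode draws actual gene identities (2,000 replicates by
default) to validate the length match (fraction of replicates with
two-sided Mann–Whitney p > 0.1 vs the candidate lengths) and to compute
expected burdened-gene and SV densities per Mbp of gene span. Gene spans
are summed directly (synthetic genes do not overlap; overlapping annotations
would need pre-merging).

**Calibration of a discrete p-value.** The null count is lattice-valued, so
the plain upper-tail mc_p is *super-uniform* under the null — P(p ≤ α) ≤ α,
with mean slightly above ½ — and no implementation can make it exactly
uniform. The calibration suite therefore checks the two properties that a
correctly calibrated discrete test must have: the randomized tie-broken
p-value P(>O) + U·P(=O) is exactly Uniform(0,1) (Kolmogorov–Smirnov over
2,000 independent null candidate draws, against a genome where burden
probability rises with gene length — precisely the confounder the matching
must remove), and the reported plain mc_p never exceeds its nominal type-I
level. The upper tail is used throughout (enrichment, not depletion, is the
alternative of interest); two-sided behavior can be obtained by doubling.

Candidate selection filters (QTL-peak membership, independent functional
evidence, evidence not derived from SV knowledge, euchromatin bounds) are
applied in order with per-filter removal counts; a named gene group can be
collapsed to a single locus spanning its extent for sensitivity analyses of
tandem arrays.

## Reproducibility and problem sizes

All randomness flows from one top-level seed through per-stage
`SeedSequence` streams; identical config + seed reproduces every output
byte for byte (hash-checked in the tests). Default problem sizes — 5 Mb,
13 strains, 300 SV loci, 100,000 MC replicates, 2,000 member replicates,
2,000 calibration draws — were chosen as the smallest scale at which every
statistic of interest is exercised with comfortable statistical resolution
on a single CPU in minutes.

## Known limitations

- The aligner targets desk-scale, mostly single-copy genomes; highly
  repetitive genomes would shed most anchors to the multiplicity filter.
- Duplications are detected as tandem re-coverage at a junction; dispersed
  duplications surface only as secondary anchors and are not called.
- Breakpoints are anchor-derived (exact to within ~tens of bp near planted
  SNPs); no base-level realignment or breakpoint-homology classification.
- Haploid assemblies only; no genotype likelihoods or heterozygous calls.
- The spacer-separated duplication and complex modes emit flagged calls but
  their truth representation (deletion + insertion pair at one locus) is a
  simplification of real nested events.
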
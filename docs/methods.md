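# Methods

This note documents the models and procedures implemented in `miratlas`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Annotation harmonization

Mature miRNA catalogues are normalized to the uppercase DNA alphabet
(U→T) and validated to lengths 15–30 nt. Identical sequences across
species collapse into one consolidated record; the representative name is
taken from the highest-precedence species (default: the target species
first, then the catalogue input order), ties broken lexicographically.

Placement on the genome is exact string matching on both strands — a
minus-strand hit is a genome substring equal to the reverse complement.
`N` bases in the genome never match, which follows directly from
zero-mismatch semantics. A sequence with more than `max_locations`
(default 10, strictly greater) total placements across both strands is
excluded entirely; a palindromic sequence placed at one position counts
once per orientation, i.e. as two locations. Exact matching is implemented
as a per-pattern scan over each contig; the test suite checks it against
an independent hash-set sliding-window oracle.

Hits are merged into loci by single-linkage clustering per (chromosome,
strand). Two hits join when `next.start < current_end + gap_tolerance`.
With the default `gap_tolerance = 0` this is pure-overlap merging —
touching intervals stay separate — and `gap_tolerance = 1` additionally
merges book-ended hits. The merge radius for "approximately the same
location" is genuinely underdetermined, so the most conservative reading
(overlap only) is the default and the tolerance is exposed in
configuration. Locus names come from the member with the best species
precedence; name collisions between loci get deterministic `-locN`
suffixes in genomic order. Merged loci are guaranteed pairwise
non-overlapping per strand.

Coordinates are 0-based half-open internally and in BED output; GFF3
output is 1-based inclusive with type `miRNA` and attributes `Name`,
`species_provenance` and `members`. The four-step funnel (input sequences
→ consolidated → aligned → loci) is reported with every run.

## Quantification

Alignment input is a 6-column BED-like table (chrom, start, end, read_id,
n_hits, strand) per sample, or minimal SAM with the `NH` tag. A placement
contributes one count to a locus when `overlap / locus_length ≥ 0.7`. The
denominator is the **locus** length by default — the coverage rule is
phrased as covering a fraction of the locus — with `read` selectable.
Counting is strand-aware by default (small-RNA protocols are stranded);
an unstranded mode is provided. Reads with `n_hits > 10` contribute
nothing; retained multi-mapped reads contribute one full count per
qualifying placement (no fractional weighting — fractional allocation is
deliberately out of scope). Counting is order-invariant, monotone in the
overlap threshold, and verified against a dense per-read × per-locus
oracle.

RPM is `count / denominator_total × 1e6` with the per-sample denominator
defaulting to reads assigned to miRNA loci, so columns sum to exactly one
million; total aligned reads is the selectable alternative. A sample with
a zero denominator yields all-zero RPM plus a warning rather than an
error.

Detection is per (locus, tissue): tissue **median** RPM strictly greater
than `detection_rpm` (default 100). The threshold mirrors the abundance
cutoff used for candidate loci, the only RPM cutoff with any external
anchor; both are configurable.

## Enrichment classification

Candidates are loci whose maximum tissue-median RPM strictly exceeds
`candidate_rpm` (default 100). For each candidate and tissue:

- fold change = `(median_t + 1) / (median_other + 1)` where `median_other`
  pools all non-tissue samples; the 1-RPM pseudocount keeps zeros finite
  and penalizes ratios built on near-empty baselines.
- p-value: one-sided Wilcoxon rank-sum (tissue > rest) by default, since
  enrichment is directional; two-sided selectable. The exact permutation
  null is used when the pooled sample size is ≤ 12 with no ties; larger or
  tied designs use the tie-corrected normal approximation on midranks.
  The switch point is fixed so the atlas-scale comparison (5 vs 75) is
  deterministically asymptotic. Fully tied data returns p = 1.
- q-value: Benjamini–Hochberg step-up, applied per tissue across
  candidates (each tissue is its own testing family); a global-BH option
  exists. TE requires fold > 5 **and** q < 0.05.
- HTE: `median_t > 5 × max` where `max` is the largest RPM value of any
  individual sample outside the tissue (the literal "maximum expression
  value observed in any other tissue"; a tissue-median-max comparator is
  available), **and** the locus is detected in ≤ 2 tissues. HTE has no
  p-value clause and is evaluated independently of TE. Class hierarchy:
  HTE1 (inequality holds in exactly one tissue) > HTE2 (two) > TE > none.
  Note that under the sample-max comparator the inequality cannot hold in
  two tissues simultaneously for the same locus unless one side is
  degenerate, so HTE2 is structurally near-empty; the class is kept for
  completeness of the hierarchy.

Sample QC reports squared Spearman correlation (ρ²) between per-sample
RPM vectors — squaring matches the convention of reporting rank-r² values
in [0, 1] — with within-tissue and between-tissue-pair means. Constant
sample vectors have undefined rank correlation; they are flagged and
excluded from the means.

Reference-miRNA stability per locus: over log2(median RPM + 1) across
tissues, %CV = 100·SD/mean with the sample (n−1) SD, and a locus is
"stable" when %CV < 10, SD ≤ 1 and mean raw tissue-median RPM exceeds the
abundance cutoff.

## qPCR ΔCt workflow

Replicate Ct values strictly above 38 cycles are censored (38.0 exactly is
retained); survivors are averaged per (sample, target). ΔCt subtracts the
arithmetic mean of the reference targets' mean Cts — equivalent to a
geometric mean of their linear quantities, standard ΔCt practice — and
relative expression is 2^(−ΔCt). Fewer than two usable references warns;
zero censors the result with a recorded reason. The alias table maps
historical alternate spellings of a target (e.g. miR-855) onto the
canonical name (miR-885) before any pooling.

Cross-platform agreement is OLS of log2(rel_expr) on log2(RPM + 1) (the
+1 handles zeros in RPM); degenerate variance on either axis returns
r² = 0 rather than NaN. %CV of reference targets is computed across
per-tissue mean Cts with the sample SD.

Panel correlation regresses, per animal, the serum marker against ALT or
AST across timepoints. The default marker axis is −ΔCt (linear in log2
expression), since relative expression itself is exponential in the latent
signal and would distort a linear fit; `rel_expr` is selectable. Animals
with fewer than 3 usable (non-censored, chemistry-matched) timepoints are
flagged not-evaluable. Serum studies may run reference-free (raw ΔCt
against a plate-level reference set chosen by the caller); the reference
set used is always explicit in the configuration.

## Synthetic-data generator

The generator emulates the *structure* of a multi-tissue atlas study:

- **Genome/annotation**: 3 chromosomes × 60 kb with 300 planted loci of
  18–25 nt at non-overlapping slots, random strand, each sequence verified
  to occur exactly once genome-wide (colliding background occurrences are
  redrawn); one extra sequence planted 11 times exercises the
  multi-mapper filter. Three species catalogues share each locus sequence
  with probability 0.5 (all three species) or carry it in a single
  species — enough to exercise consolidation, provenance and
  representative naming.
- **Counts**: negative binomial with Var = μ + φ·μ², φ = 0.1 (a typical
  bulk RNA-seq replicate dispersion), at 10⁶ counts per sample over
  16 tissues × 5 replicates. Baselines are true RPM: planted
  highly-enriched loci get a low off-tissue abundance (≈ 5–6 RPM,
  log-normal), references a high stable one (≈ 5000 RPM), and the
  remaining loci are log-normal (log2 mean 8, SD 2) rescaled to fill the
  rest of the million-read budget, so realized RPM tracks the planted
  baseline to within a few percent. Planted enrichment multiplies the
  mean in one tissue: fold 50 for HTE1 loci (20), fold 10 for TE loci
  (30).
- **Reads**: per-sample alignments drawn multinomially from the planted
  expression, shifted by at most 15 % of the locus length so every signal
  read passes the 70 % rule exactly once; a decoy fraction (10 %) fails
  counting by construction (off-locus placements and multi-mapper reads).
  Read-level files are generated for one replicate per tissue at 2×10⁴
  reads to keep them small; the deep count matrix is generated directly.
- **qPCR**: Ct = 36 − log2(expression) + N(0, 0.15), triplicates, clipped
  at an instrument ceiling of 40 cycles (distinct from the 38-cycle
  analysis cutoff). With σ = 0 the model inverts exactly, which the tests
  use as an identity check.
- **Injury panel**: 2 injured + 4 control animals over days 1/7/14 ×
  pre/post dose. A latent injury level z rising to 2.0 drives both
  chemistry (ALT = 30 + 60z ± 3, AST = 35 + 90z ± 4 U/L) and liver-target
  Ct (−2.5 cycles per unit z ± 0.2); non-liver targets and controls are
  flat. Shared signal plus independent noise yields the planted
  co-elevation while keeping control r² at noise level.

Every generator draws from its own stream seeded by (seed, stage), so
outputs are bit-reproducible and independent of call order.

What the generator does **not** emulate: sequencing error and adapter
artifacts, mapping ambiguity beyond the planted multi-mapper, GC/length
bias, hairpin precursors and isomiRs, cross-hybridization in qPCR,
amplification-efficiency differences, batch effects, or biological
covariance between tissues. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under idealized noise —
not that real atlas data would behave as cleanly.

## Numerical choices and degenerate inputs

- All strict inequalities follow the stated thresholds: > 100 RPM,
  > 5-fold, > 10 locations, > 38 cycles, q < 0.05; every boundary case is
  pinned by a test.
- p-values are clamped to (tiny, 1]; BH output is capped at 1 and
  order-preserving.
- Ties in locus naming, cluster ordering and record ordering are broken
  deterministically (genomic order, then lexicographic).
- Degenerate inputs: all-tied rank-sum data → p = 1; constant vectors in
  correlation → flagged/excluded (Spearman) or r² = 0 (OLS); zero-depth
  samples → zero RPM plus warning; fully censored Ct → explicit censored
  result, never NaN arithmetic.

## Problem sizes

The shipped defaults (300 loci, 16 × 5 samples, 10⁶ counts/sample, 20-seed
null calibration, 2 × 10⁴-read alignment files for 16 samples) keep the
full test suite under a minute of compute while preserving the design
shape of an atlas study; all sizes scale through `SimulationConfig`.

## Known limitations

- No mismatch-tolerant or seed-and-extend alignment; annotation transfer
  is limited to perfectly conserved mature sequences.
- No fractional multi-mapper allocation and no dispersion-shrinkage
  differential-expression modeling; the rank-sum test is the inferential
  workhorse by design.
- HTE2 is structurally near-empty under the default comparator (above).
- The ΔCt workflow assumes equal amplification efficiency across targets;
  no standard-curve modeling.
- The panel analysis treats timepoints as exchangeable observations in an
  OLS fit; it does not model within-animal autocorrelation.
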
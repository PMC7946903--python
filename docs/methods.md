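# Methods

This note documents the models, defaults and numerical choices behind
`methylfoot`, and what the synthetic validation does and does not show.

## Data model

All coordinates are 0-based half-open. A CpG site is anchored at the C of
the plus strand and occupies `[pos, pos + 2)`; plus/minus strand
bisulfite evidence is assumed to be pre-merged by the producer of the
input tracks. Methylation ratios live in [0, 1]; missingness is explicit
(NaN) and never conflated with 0 methylation. Tools that encode
missingness by shifting values +1 and using 0 as a sentinel are supported
as an I/O convention only (`shift_plus_one` / `unshift_minus_one`);
averaging the available entries of the shifted representation and
un-shifting is algebraically identical to the native NaN-aware mean,
which is what all profile code computes.

Two track dialects are read: `bismark-cov` (chrom, start, end, percent,
n_methylated, n_unmethylated) and `bedgraph-pair` (a ratio bedGraph plus
a coverage bedGraph). Per-sample tracks are combined over the union of
their sites; values absent in a sample are missing.

## Per-CpG test and DMR assembly

The per-CpG two-group comparison is a two-sided Mann-Whitney test. With
the default 4-vs-6 replicate design the exact null is enumerable — all
C(10, 4) = 210 assignments of the pooled mid-ranks to group A — and the
p-value is the fraction of assignments whose rank-sum deviation from its
expectation is at least the observed one. Enumeration is used whenever
C(nA+nB, nA) ≤ 50,000; beyond that the tie- and continuity-corrected
normal approximation takes over. For genome-scale calling the
enumeration is vectorised: sites are grouped by missingness pattern and
each group's p-values come from one rank-matrix × assignment-matrix
product. The scalar and matrix paths are tested for equality, and both
against an independently written brute-force enumerator.

A CpG qualifies when p ≤ `alpha` (default 0.05) **and**
|mean(A) − mean(B)| ≥ `min_diff` (default 0.25), means taken over
non-missing replicates; CpGs with fewer than two observed values in
either group are untestable and never qualify. Runs of at least
`min_consecutive` = 2 qualifying CpGs — consecutive rows of the filtered
table, all with the same difference sign, each within `max_gap` = 500 bp
of the previous — become one DMR. The core span runs from the first
qualifying CpG to the end of the last CpG's dinucleotide; the reported
interval adds `extension` = 100 bp per side, clipped to the chromosome.

Choices worth making explicit:

- **alpha = 0.05, no per-CpG multiple-testing correction.** The exact
  test's floor at 4-vs-6 is 2/210 ≈ 0.0095, so any correction factor
  above ~5 would leave no CpG able to qualify; significance acts as a
  screen and the `min_diff` effect-size requirement carries the
  specificity. Both are configurable.
- **`min_diff` is evaluated per CpG**, not on the region mean — the
  stricter and more reproducible reading of "two consecutive CpGs with
  ≥25% difference".
- **`max_gap` = 500 bp** prevents joining qualifying CpGs across
  CpG-free deserts into spurious multi-kb regions.
- **Uniform sign within a run**: a direction flip terminates the run, so
  no DMR mixes hypo- and hyper-methylation.
- **Count non-monotonicity.** Tightening alpha (or raising `min_diff`)
  shrinks the *set of qualifying CpGs* monotonically, and with it the
  total CpGs captured in DMRs — but the *number of regions* can
  transiently rise when a borderline CpG drops out of the middle of a
  run and splits it in two. This is a property of any
  consecutive-run rule; the monotonicity tests therefore pin the nested
  quantity (captured CpGs, and spike counts, which are monotone).

Filters after calling, in order: blacklist (any overlap removes),
repeats (removed when covered fraction > 0.5), autosomes only
(default on; simulated `chrS*` chromosomes count as autosomes),
mean mappability < 0.8 removes (uncovered spans count as mappability 0).
Control regions are drawn length-matched per DMR, CpG-count-matched
within ±20% (verified by direct recount), non-overlapping with DMRs and
passing the same filters, with a bounded retry budget and a fixed seed.

## 5mC-spike screen

Input is the per-CpG mean over non-missing samples of a single cell
type, after keeping only CpGs with coverage strictly above 5 reads in at
least half the samples. Scanning consecutive CpGs with both neighbour
gaps strictly below 100 bp: a candidate peak rises by more than 0.5 over
its left neighbour; if another CpG starts within 6 bp it is combined
with the peak (unweighted mean — the screen operates on the averaged
track, so coverage weighting does not apply); the spike is emitted iff
the (combined) peak ratio exceeds both the left and the next CpG beyond
the unit by more than the thresholds. Hence every spike is at most
`merge_window + 2` = 8 bp wide and each CpG belongs to at most one
spike. The >50% rise/fall is an absolute ratio change: ratios are
bounded in [0, 1], so a relative (fold) reading would explode near 0.
The fall is measured from the combined mean when merging occurred, and
the falling flank must also lie within the 100-bp neighbour distance —
both read symmetrically with the rise. Merging considers a single
additional CpG; chains are not extended.

Cross-cell-type comparison labels a spike *specific* when it overlaps
(≥ 1 bp) no spike of any other cell type and *common* otherwise, with
pairwise counts reported from each set's own perspective (overlaps need
not be one-to-one, so a symmetric single count would double-book).

## Region toolkit

Classification gives TF binding precedence: a DMR overlapping any TF
ChIP peak is `TF_peak`; of the remainder, ATAC overlap makes it `open`,
else `no_peak` — mirroring a workflow that removes TF-bound regions
first and splits the rest by accessibility. Any-overlap (≥ 1 bp)
semantics; fraction thresholds are used only where stated (repeats).
Quintiles rank regions by group-A mean methylation (stable descending
sort, ties broken by genomic order) into five near-equal bins, the first
`n mod 5` bins one larger. Genomic-location annotation decides by region
midpoint with priority promoter > TTS > exon > intron > intergenic;
promoter and TTS windows default to ±1000 bp around the TSS and
transcript end (deliberately exposed as parameters — external annotators
bake in their own windows). Interval queries run on per-chromosome
interval trees and are tested against quadratic oracles.

## Profiles

A profile is a (region × offset) matrix with explicit missingness;
the reported curve is the per-offset mean over available entries with n
and a normal-approximation 95% CI (1.96·SD/√n, defined for n ≥ 2).
Region centers are `floor((start+end)/2)`; motif-centered profiles use
the best hit's window midpoint, ties broken toward the region center.
Rows of minus-strand regions are flipped so motif orientation is
uniform. A CpG's value is assigned to both bp of its dinucleotide: CpG
methylation is a property of the strand-symmetric CG unit, and this
makes the oriented core profile exactly invariant under strand flips
(a minus-strand motif instance's core CpG covers the same oriented
offsets {0, 1} as a plus-strand one). Coverage profiles treat the
bedGraph as a step function and average it over fixed-width bins
(default 25 bp) per region.

## Motif statistics

Scoring: `score(w) = Σ_i log2(P_motif[i, w_i] / P_bg[w_i])` in bits on
both strands, windows containing N skipped; probability columns get a
0.01 pseudocount before logs. The default hit threshold is 60% of the
motif's maximum achievable score — thresholds inherited from external
motif tools are not recoverable, so the fraction is explicit and
per-motif configurable in bits. JASPAR-format count matrices are read
via Biopython.

Enrichment counts region presence/absence (≥ 1 hit at threshold on
either strand), tests over-representation with the hypergeometric upper
tail on the target+background universe and corrects across motifs with
Benjamini-Hochberg. Fold enrichment is the ratio of containing
fractions (0 when the target has none; infinity guarded when the
background has none). Co-association reduces hits to motif-class
presence per region; hits of different classes whose starts lie within
4 bp count once, keeping the higher score — a documented approximation
of a minimum inter-motif spacing rule. Node size = % of regions
containing the class; edge = % containing both; the summary reports the
% of regions with ≥ 2 classes and with ≥ 1.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not real genomes:

- **Chromosomes**: i.i.d. background sequence with accidental CG
  dinucleotides scrubbed, so the emitted CpG list is exactly the CpGs
  present. Background CpGs are planted at `background_cpg_rate`
  (default 10/kb) and CpG islands (default 10/Mb, 600 bp, ~10 bp
  spacing) on top.
- **Planted DMRs** get their own CpG ladder (~60–80 bp spacing), the
  generator's rendering of the CpG enrichment of regulatory regions; it
  also guarantees each region carries several testable CpGs, as real
  DMRs do.
- **Noise model**: per condition each CpG has a true ratio mu
  (background 0.75; inside a planted DMR, the spec's baseline in
  condition A and baseline − delta in B). Replicate ratio ~
  Beta(mean mu, precision kappa = 100); coverage ~ NegBin(mean 30,
  dispersion 10); methylated reads ~ Binomial(coverage, replicate
  ratio); dropout 1%. Beta-binomial is the standard overdispersed
  bisulfite count model and makes replicate scatter tunable.
- **Protected CpGs** keep their level (default 0.9) in *both*
  conditions while the surrounding DMR CpGs drop — the
  demethylation-protection footprint. When a motif is planted in the
  region, the protected CpG is the motif-core CpG (the bundled
  EGR-like consensus GTGGCGTGG carries a single central CpG; the
  AP1-like TGACTCA none).
- **Determinism**: every replicate draws from its own RNG stream
  derived from the master seed and the sample name by stable hashing —
  adding replicates never perturbs existing ones; identical configs are
  bit-identical.

Study presets freeze the validation conditions: `dmr_study` (2 × 1 Mb,
~21k CpGs, 30 DMRs of 300–800 bp at delta 0.4 from baseline 0.85, 4 vs 6
replicates), `null_study` (no planted effects), `spike_study` (50
protected CpGs at 0.9 inside regions demethylated 0.9 → 0.1),
`footprint_study` (spike study + 50 planted motif instances on random
strands) and `demo` (1 × 300 kb for fast end-to-end runs). These sizes
keep a full validation cycle in tens of seconds while leaving dozens of
independent planted features per run.

What passing these tests shows: the implementations compute what their
definitions say, at effect sizes and coverages where the signal is
clearly separable. What they do not show: performance on real WGBS
features the generator omits — non-stationary CpG density and
methylation landscapes, strand-asymmetric artefacts, bisulfite
conversion errors, hydroxymethylation mixtures, mapping bias and
copy-number structure.

## Pipeline

`methylfoot run` executes simulate → union/filter → call-dmrs →
call-spikes → classify/quintiles → motif-centered profiles → motif
statistics from one YAML config (all thresholds default to the module
defaults above), logs per-stage record counts, and writes a manifest
with a sha256 checksum per output so reruns are verifiable byte for
byte. `--resume` rewrites only missing outputs; since every stage is a
pure function of config + seed, resumed outputs are identical. Exit
codes: 0 success, 2 validation, 3 missing input, 4 internal.

## Known limitations

- The DMR caller is the run-based rule above, not a smoothing or
  beta-binomial-regression caller; there is no region-level FDR.
- The spike screen runs on averaged tracks and carries no per-spike
  statistical test.
- Enrichment backgrounds are taken as given; no GC- or
  dinucleotide-matched background shuffling.
- Motif hit counts depend on the explicit threshold convention; they
  are not comparable to external tools' counts without matching
  thresholds.
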
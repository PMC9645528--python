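# Methods

This note documents the models and procedures `mirproc` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the procedures leave room.

## Coordinate conventions

Genomic coordinates are 0-based half-open throughout the library; GFF3 I/O
converts to/from that format's 1-based inclusive system at the boundary.
Precursor-local positions (mature arm intervals, cleavage points, cut
sites) are 1-based inclusive, matching the "between bases 22 and 23" way
cleavage sites are described in the literature. The two cleavage points of
a hairpin are `cp_5p3`, the last nucleotide of the 5p arm, and `cp_3p5`,
the first nucleotide of the 3p arm; when both mature arms are annotated
they are derived from the arm boundaries. T is silently mapped to U on
input because oligo tables and genome FASTA mix DNA/RNA conventions.

## Hairpin geometry

`cleave_hairpin(seq, cut5, cut3)` splits a precursor into
`seq[1..cut5]` (5p strand), `seq[cut5+1..cut3-1]` (loop) and
`seq[cut3..L]` (3p strand); the loop must be non-empty. Concatenating the
three products always reproduces the input.

`fold_stem` is a contiguous-pairing model, **not** a thermodynamic folder:
for every pair of 5′/3′ end overhangs up to `max_end_overhang` (default 4)
it pairs the trimmed termini inward while bases are Watson–Crick
complementary (G·U wobble is opt-in) and at least `min_loop` (default 3,
the minimal physical loop) unpaired bases remain, and returns the geometry
maximizing stem length (ties: smallest total overhang, then smallest 5′
overhang). On perfect-duplex substrates this recovers the designed
geometry exactly; on natural hairpins with bulges it reports only the
terminal helix, so stem/loop deltas (`mirtron_extension_score`) are a
descriptive approximation rather than an MFE computation. The default
reference geometry for mirtron extension calls is a 22 bp stem / 10 nt
loop canonical hairpin; `extended` means either delta is positive.

## Trimming

The trimmer reproduces the published two-program layout: 4 random bases
removed from the left, then up to 2 rounds of 5′-adapter
(`GTTCAGAGTTCTACAGTCCGACGATCNNNN`) and 3′-adapter
(`NNNNTGGAATTCTCGGGTGCCAAGG`) removal, terminal-N trimming, then length
(≥ 12) and N-fraction (≤ 0.1) filters. Matching is semi-global,
mismatch-only (no indels), with mismatch fraction ≤ 0.075 over an overlap
≥ 14; N matches anything when wildcards are on. Ties among equally valid
3′-adapter matches prefer the longest trimmed suffix (leftmost match).
This is an approximate re-implementation of the cutadapt invocation those
parameters come from: the parameters are pinned, the matcher internals are
not, and byte-exact cutadapt parity is a non-goal. The 3′-side 4N is
included in the adapter pattern as printed, so it is removed by the
adapter match itself.

## Counting and normalization

Only reads of 19–25 nt are counted. An alignment is assigned to a feature
only with sense-strand overlap ≥ 15 nt. A read with `n` reported
alignments (NH tag; absent ⇒ 1) whose alignment overlaps `m` qualifying
features contributes `1/(n·m)` to each, so every fully annotated read has
total mass 1 — the behavior of fractional multi-overlap counting flags in
featureCounts-style tools.

Size factors are plain median-of-ratios over features detected in every
sample (fallback: total-count scaling with geometric mean 1, with a
warning). `baseMean` is the mean of size-factor-normalized counts over all
samples; `log2fc = log2((meanB + pc)/(meanA + pc))` with pseudocount 0.5
by default. No dispersion estimation, no Wald/LRT testing and no fold
change shrinkage are performed — the downstream classification consumes
baseMean and plain fold changes only. Two consequences worth knowing:

* median-of-ratios is biased when the dysregulated features are a large
  share of the panel (with 2 planted features among 10, the median shifts
  by a full order statistic, ~0.3 log2); this matters for tiny synthetic
  panels, not for a real miRNome;
* the unshrunk log2fc estimator at n=3 replicates with negative-binomial
  dispersion ~0.1 carries a finite-sample bias of roughly half its
  sampling SD. Recovery tests therefore assert per-run agreement within 3
  sampling SDs rather than unbiasedness of the mean.

CPM scaling exposes the denominator as a choice (`all_counted` 19–25 nt
reads, or `length_21_23`) because counting selects 19–25 nt while some
figures normalize per million of 21–23 nt reads.

## Strand sorting

The six rules run in a fixed order (pairing, external annotation,
`single_miRNA`, `lowExp`, dominance, cross-experiment reconciliation); the
order is semantic — a pair with baseMeans (0.2, 0.05) is `lowExp`, never
miRNA/miRNA*. "At least double" is implemented as ≥ 2× (a ratio of exactly
2 is decisive); equal baseMeans are `notClear`. The baseMean threshold
0.25 is applied per experiment on the jointly computed baseMean; both the
threshold and the ratio are configurable. External miRNA/miRNA* type
annotation is honored only when a pair carries both labels. Mirtron
membership is an input list (a published set), not derived.

## Cluster calling

Per replicate: alignments of 21–23 nt reads are weighted 1/n, collapsed
into maximal overlapping regions (weights summed), regions below 3 RPM are
discarded, and survivors within 50 bp are joined transitively. "Within 50
bp" is inclusive (end-exclusive gap ≤ 50, so distance 0 = adjacency). The
RPM denominator is the replicate's total weighted 21–23 nt alignment mass,
configurable. Clustering is strand-blind by default (a strand-aware mode
exists). Filtering precedes joining, as the procedure is stated. The
genotype set keeps only clusters with an overlapping cluster in every
replicate, with union coordinates; annotation assigns the
highest-priority overlapping layer (miRNA > TE > mRNA > miscRNA, any
overlap ≥ 1 nt), else `other`.

## Cleavage fidelity

For each miRNA passing the baseMean ≥ 100 gate, read 5′ starts are tallied
around `cp_3p5` (3p arm) and read 3′ ends around `cp_5p3` (5p arm) in a
±15 nt window, per replicate, for 19–25 nt reads. Offsets are oriented
5′→3′ along the mature miRNA on both genomic strands, so positive offsets
always mean a shortened mature. The canonical CP is redefined from
wild-type data only: median count across replicates per position, argmax;
the canonical CP is kept on empty windows, ties at the maximum, or shifts
beyond ±7 nt. Medians over an even number of replicates are the mean of
the central values, and the median is taken over raw counts (the procedure
mentions no normalization before the argmax).

Counts at the new CP ± 5 are converted to **window-local densities** (unit
sum over the 11 positions; an undefined zero-count row is all-zero and
flagged) and the wild-type row is subtracted from the mutant's, so every
difference row sums to zero and rows are comparable across miRNAs of
different abundance. Window-local normalization is one of two defensible
readings of "re-calculated into read densities" (the other being
library-scaled); it is the default and configurable. Top-k selection ranks
by |difference at the CP| in the selecting dataset and orders the picked
rows by the signed CP difference in the ordering dataset (signed by
default; configurable). `recovered_shift` reduces a difference row to the
offset of its maximal positive entry (ties → smallest |offset|) and is the
summary used in recovery tests.

## Partial processing

Reads sense-overlapping a precursor are matched, most specific span first,
against templates built from the precursor boundaries and the two CPs with
a per-boundary tolerance of ±2 nt: precursor, partial 5′ fragment
(5′ boundary → `cp_3p5 − 1`: the single-cut product left when only the 5′
end of the 3p miRNA is cleaved), partial 3′ fragment, miRNA-5p, miRNA-3p,
loop fragment, other. The seven-category set is a reconstruction: the
source procedure defines its categories by reference to a figure, and this
enum is the minimal complete partition implied by "boundaries plus the two
cleavage points", with the precedence order making assignment unambiguous.
Percentages are over all overlapping reads and sum to 100 whenever any
read overlaps.

## Synthetic data generator

The generator emulates the structure of a multi-replicate wild-type vs
mutant small RNA experiment. Defaults (chosen once as study-like
conditions): 20 canonical loci, 3 replicates per genotype, 10⁴ reads per
replicate, per-locus log-normal(0, 1) expression, negative-binomial
replicate noise with dispersion 0.1 (0 ⇒ Poisson), 3p arm fraction 0.5,
wild-type 3p 5′-offset distribution {−1: 0.05, 0: 0.90, +1: 0.05} vs
mutant {−1: 0.05, 0: 0.55, +1: 0.05, +2: 0.35} (5′-end variability of the
3p miRNA), partial-fragment fraction 0.05 wild-type vs 0.15 mutant (the
mutant's partial-cleavage excess is reported qualitatively in the
literature; these magnitudes are our choice), read lengths peaked at 22 nt
over 19–25. Mirtron-like loci draw stems of 30–35 bp and loops of 15–20 nt
(extended relative to the 22/10 canonical geometry); inverted-repeat
cluster sources emit 21–23 nt reads across a 300-nt region and carry no
miRNA annotation; duplicated loci share an identical sequence and their
reads are reported once per copy with NH=2. Optional per-locus expression
multipliers apply to the mutant condition only (planted fold changes).

One seeded stream drives the reference build; one stream per
(seed, condition, replicate) drives read generation, drawing in a
documented order (locus counts, then per-read category/arm/offset/length),
so all outputs are bit-reproducible. Alignments are emitted directly as
SAM with NH tags — read placement is exact by construction, which keeps
genome alignment out of scope while preserving every downstream contract.
FASTQ output uses the NEXTflex layout (4 random bases + insert + 4 random
bases + 3′ adapter), so trimming recovers exactly the truth inserts.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: sequencing errors and quality
variation, alignment ambiguity beyond exact duplicates, RNA degradation
background, exonucleolytic trimming of read ends, expression correlation
between arms beyond the planted ratio, and genome-scale annotation
complexity (overlapping genes, repeats). Recovery results demonstrate the
correctness of the analysis logic under the stated statistical model, not
robustness to those artifacts.

## Problem sizes in the test suite

The statistical acceptance tests run 20 seeded simulations at 10⁴ reads ×
3 replicates × 2 genotypes over a 12-locus panel (planted features kept a
small minority of the panel so median-of-ratios normalization behaves as
it does on a real miRNome), plus 100-instance brute-force oracle
comparisons for clustering and counting. Binomially planted quantities
(arm ratio, partial fraction) are checked pooled across seeds at 3 SD with
at most the expected rare per-seed 3 SD outlier; fold changes are checked
per run at 3 sampling SDs (see the normalization section for why the mean
is not asserted unbiased).

## Known limitations

* `fold_stem` reports only the terminal contiguous helix; internal loops
  and bulges truncate the stem estimate.
* The trimmer has no indel handling and no quality trimming.
* Differential-expression p-values are out of scope by design; the
  pipeline's fold changes are unshrunk.
* Fidelity analysis cannot distinguish an altered Dicer cleavage point
  from altered strand selection among existing isomiRs; it quantifies the
  read-end shift either way.
* The partial-processing category set is a reconstruction (see above) and
  should be read as such when comparing to figure-defined categories.
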
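# Methods

This note documents the models, conventions and numerical choices behind
`amplimeth`, in the order the pipeline runs them.

## Trend-gene selection along the adenoma–carcinoma sequence

Samples carry an ordinal stage code (normal = 0, adenoma = 1, carcinoma = 2).
For each gene the tie-corrected Kendall rank correlation (tau-b) of log2
expression against the stage code measures graded change; tau-b is the right
variant because the stage variable is massively tied (tens of samples share
each of three codes).  The stage codes are rank-based inputs, so any strictly
increasing recoding leaves tau unchanged — the 0/1/2 spacing is documentation,
not a parameter.

Pairwise group differences use the two-sided pooled-variance Student t-test
(Welch's form is available via `welch=True`), with Benjamini–Hochberg step-up
adjustment applied across genes **within** each comparison (normal-vs-adenoma,
normal-vs-carcinoma, adenoma-vs-carcinoma); pooling across comparisons would
mix tests with different power and is not standard.  Effect size is the
difference of group mean log2 intensities ("logFc" in microarray parlance).

A gene is selected as a marker when

* |tau| ≥ `tau_min` (default 0.5), and
* in at least one normal-vs-lesion comparison, BH-adjusted p < `alpha`
  (default 0.05) **and** |logFc| > `logfc_min` (default 1.0) in that same
  comparison.

The tau threshold deserves a caveat: descriptions of this selection strategy
sometimes print the interval as −0.5 ≤ tau ≤ 0.5, which read literally keeps
the *non*-trending genes.  `amplimeth` implements the |tau| ≥ 0.5 reading and
exposes `tau_min` so the rule is never silent.  Genes are additionally binned
by the two-set Venn logic over the normal-vs-adenoma and normal-vs-carcinoma
adjusted p-values (`both`, `AD_only`, `CRC_only`, `neither`).

The demethylation (5-Aza) re-expression screen is the two-condition special
case: logFc = mean(treated) − mean(control), a gene flagged re-expressed when
logFc > 1.  Note the sign convention: re-expression after a demethylating
agent means *higher* expression in treated cells, so the subtraction is
treated-minus-control regardless of how the rule is sometimes written.

## CpG island prediction

A window of 100 nt slides in steps of 1 nt.  A window is island-like when
GC% > 50 and the observed/expected CpG ratio
(#CG · window length) / (#C · #G) exceeds 0.6 (the Gardiner-Garden & Frommer
statistic).  Overlapping or book-ended marked windows are unioned and merged
spans of ≥ 200 nt are reported with the mean GC% and Obs/Exp of their member
windows.  All five parameters are exposed.  N bases count toward window
length but not toward any C/G/CpG count; a sequence shorter than the window
warns and returns no calls.  The union-merge rule is the simplest convention
that is exactly reproducible; no claim of bug-for-bug parity with any
external island finder is made, and coordinates are 0-based half-open.

## Bisulfite alignment

Bisulfite conversion turns unmethylated C into T while 5-methyl-C stays C.
Instead of penalizing reads for methylation state, the template is converted
once into two reference forms:

* forward: non-CpG C → T, CpG C → wildcard **Y** (matches read C or T at
  full match score);
* reverse (the converted complementary strand written in plus orientation):
  non-CpG G → A, CpG G → wildcard **R** (matches A or G).

Reads are aligned with the Smith–Waterman local algorithm under Gotoh's
three-state affine-gap recurrence (H/E/F matrices), against the forward
reference directly and against the reverse reference after
reverse-complementing the read; the higher-scoring orientation is reported
and ties go to forward.  Both strands are always tried because the
sequencing direction of a library is not, in general, known to the caller.

Scoring defaults are match +1, mismatch −1, gap-open −2, gap-extend −1 (a
gap of length k costs open + (k−1)·extend); all configurable.  The maximum
attainable score of a read is match × read length — a gapless perfect
full-length match — which makes the score fraction read-length normalized.
Reads with score fraction ≥ 0.80 (inclusive) are retained; the threshold is
the conventional read-retention rule for amplicon pyrosequencing data.
Traceback tie-break, for reproducibility: prefer the diagonal step, then
consuming a read base (gap in template), then consuming a template base; the
first-encountered maximal cell in row-major order anchors the traceback.
The DP inner loop is numba-jitted; an exhaustive enumeration oracle over all
local alignments of short strings verifies the recurrence in the tests.

## Methylation calling and comparison

At each CpG column of a passing alignment the read base is counted:
C → methylated, T → unmethylated (on reverse-orientation alignments the
complementary G/A at the CpG's G position carry the same information).  Gaps
and unexpected bases (A/G on the forward strand) go to `count_other` and are
excluded from the fraction denominator — they indicate sequencing error or
misalignment, not methylation state.  Sites inside primer masks are excluded
entirely because primer-derived bases carry the primer's sequence, not the
molecule's methylation.  The methylation fraction is count_C/(count_C +
count_T), undefined at zero coverage.

Assay-level summaries are unweighted means over the assay's CpG sites on the
0–100 percent scale (coverage weighting available behind a flag).  Group
comparisons reuse the pooled-variance t-test; an assay is hyper- or
hypomethylated in a lesion group when its mean is above/below the NAT mean
with p < 0.05.  Hierarchical clustering of the assay × sample matrix
defaults to Euclidean distance with average linkage after per-row mean
imputation of missing cells; rows are sorted by id before linkage so the
result is invariant to input row order, and flat partitions come from
cutting the dendrogram at a requested group count.

## miRNA Ct normalization

Raw Ct values (valid range (0, 45]) are inverted to 45 − Ct so larger means
more abundant.  Interplate calibration subtracts each plate's calibrator
deviation from the across-plate calibrator mean from every well of that
plate (mean-centering; a reference-plate convention would differ only by a
global constant).  Reference normalization then subtracts each sample's
miR-423-5p value.  Inversion commutes with both corrections, so its place in
the chain is a presentation choice; calibration strictly precedes reference
normalization.  Undetected wells stay missing — imputing them at the maximal
cycle would fabricate signal and is deliberately not done; samples missing
the reference are flagged and excluded from comparisons.  Differential
miRNAs can be ranked by how many genes of a supplied gene set they target
according to a user-provided prediction table (count descending, id
ascending — deterministic).

## IHC Quick-score

Q-score = percent positive cells (0–100) × staining intensity (0–3), range
0–300.  Each core carries a single dominant intensity (an H-score-style sum
over intensity bins is a different statistic and is not implemented).  Group
summaries report mean ± SD and whether the means are strictly monotone along
NAT → AD → CRC; a missing group breaks any trend claim.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analysis assumes,
with recorded ground truth:

* **Expression**: per-gene baselines uniform on [3, 12] log2 units (the
  intensity range of the emulated arrays), planted genes stepping by
  `step_effect` per stage (defaults: 1000 genes, 10 samples/stage, 25 up +
  25 down at 1.5 log2 units, Gaussian noise SD 1.0 — the conditions under
  which selection performance is measured).  Real microarray data add
  probe-level correlation, heteroscedasticity and batch structure that the
  generator does not model, so recovery rates here measure the selection
  rule, not array preprocessing.
* **Reads**: full-amplicon-length reads (amplicon sequencing, no
  fragmentation) from the forward strand.  Per read, CpG cytosines stay C
  with the site's methylation probability; other cytosines convert with
  probability `conversion_efficiency`; substitutions and indels are applied
  per base, the indel rate multiplied by `homopolymer_multiplier` (default
  3) inside runs of ≥ 3 identical bases — the characteristic homopolymer
  error mode of 454-style pyrosequencing.  Run threshold 3 and the
  multiplier are modelling choices; published per-run error rates for this
  chemistry vary, so defaults are parameters, not claims.  Three independent
  seed streams (`default_rng([seed, k])`, k = 0 methylation / 1 conversion /
  2 errors) make the planted binomial draws independently replayable.
* **Ct panels**: Ct = miRNA base (uniform 24–34) + plate offset + planted
  group shift + Gaussian noise (default SD 0.25 cycles); miRNAs are split
  across plates and each plate carries one calibrator well at base 20 plus
  the plate offset.  Default design 40 miRNAs, 3 samples per group — the
  small-panel FFPE setting the normalization chain targets.
* **Q-score cores**: intensity ⌈mean/100⌉, percent = mean/intensity + noise
  clipped to [0, 100], so noise-free cores reproduce the requested group
  means exactly.

Zero-noise generators reproduce their parameters exactly, which is what the
exact-recovery tests exploit; passing them shows the estimators are unbiased
under the assumed model, not that the model captures every property of real
tissue data.

## Problem sizes and determinism

Simulation-based checks run at sizes chosen to make their statistical
guarantees sharp while staying desk-scale: 500 random short pairs for the
alignment oracle, 500 reads × 100 replicates for methylation recovery,
1000 genes × 20 seeds for trend recovery, 1000 random vectors for the BH
oracle.  The full pipeline threads one global seed through named per-stage
substreams (`SeedSequence([seed, index])`), writes only plain-text
artifacts, and emits no timestamps into summaries, so a configuration and
seed determine the report bundle byte-for-byte.

## Known limitations

* The aligner searches both orientations but scores base space only; no
  flowgram-space or quality-aware alignment.
* No beta-binomial or region-level differential methylation model — group
  comparison is a t-test on assay means, mirroring the per-assay reporting
  the pipeline reimplements.
* The prediction-table ranking is a set intersection; it performs no target
  prediction itself.
* Read simulation covers one strand and one amplicon per call; chimeric
  reads, PCR duplicates and bisulfite over-conversion artifacts are not
  modelled.
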
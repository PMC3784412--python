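# Methods

This note records the models, conventions and design choices behind
`chromnest`, in the order the pipeline applies them.

## Coordinates and gene ordering

Intervals are 0-based half-open internally. The annotation reader defaults to
1-based inclusive input (the convention of printed tables and Ensembl-derived
exports); BED-derived input is accepted with `one_based=False`. The off-by-one
between conventions is far below the precision at which spans are reported
(0.1 kb), and the KB formatter (`span_kb` / `format_kb`) rounds half away from
zero, printing one decimal below 1,000 kb and whole kb above.

Genes are ordered per chromosome by (start, end), stably; strand is carried
but ignored by every score, because all region computations use the
strand-agnostic span from transcription start to transcription end.

Overlapping transcripts are collapsed before windowing: transitively
overlapping genes form a group (a chain A–B, B–C merges all three) and one
representative is kept — the gene with the most Present detection calls,
ties broken by longest interval, then lexicographically smallest identifier.
This keeps the most informative expression profile and is deterministic.
Output is verified overlap-free by a quadratic brute-force check in the tests.

## Expression model

The matrix carries log2 intensities and Present/Marginal/Absent detection
calls per gene × sample, with (tissue, timepoint, replicate) metadata.
Conventions:

* genes with fewer than 5 Present calls are removed (a correlation needs at
  least 5 points);
* Marginal counts as not-Present (conservative MAS5 reading);
* raw intensities are floored at 1.0 before log2 so synthetic zeros stay
  finite;
* a gene is "expressed in a tissue" when Present in **all** of that tissue's
  replicates (an `any` rule is selectable — used where a looser
  "detectable" reading is wanted for cross-tissue sharing);
* pairwise correlation is Spearman by default (Pearson selectable); a
  zero-variance profile makes the correlation undefined, which propagates as
  missing, never as zero.

## Distance-binned co-expression

Same-chromosome gene pairs are binned by the distance between their start
sites (10-kb bins to 60 Mb by default; a pair 351 kb apart lands in the
350–360 kb bin, half-open). Bin means drop undefined correlations from both
numerator and denominator; empty bins are reported with `n_pairs = 0`. The
cross-chromosome baseline enumerates all different-chromosome pairs up to a
cap (2,000,000 by default), beyond which it subsamples uniformly with a
recorded seed and reports the standard error of the estimate. The output
table carries the out-of-range and cross-chromosome pair counts so that total
pair count conservation can be audited.

## Neighborhood scoring

Candidate neighborhoods are runs of 2–10 consecutive probed genes (windows
never span chromosomes, and unprobed genes are invisible: windows run over the
probed-gene sequence).

* **ANC** — mean of all C(k,2) pairwise correlations. Any undefined pair
  makes the window unscorable: ANC and TNS are reported missing (not 0) and
  the window is excluded from distribution tests.
* **SS** — the fraction of comparison genomes in which every window gene maps
  to one common syntenic block. Genes missing from a genome's map break
  synteny there. The denominator is the number of comparison genomes only
  (the reference is trivially syntenic with itself). Gene order within the
  block is not required to match — block membership already encodes
  order at the block-builder's resolution — but a strict-order mode
  (order indices stepping ±1 in one direction) is available.
* **p** — the permutation null shuffles expression profiles across genome
  positions with the annotation fixed, recomputes window ANCs, and pools the
  null over windows *conditioned on window size k* (pooling across sizes
  would mix distributions with different variances). p uses the plus-one
  estimator, (1 + #{null ≥ observed}) / (1 + n_null), so it is never zero.
  Tiny inputs can use exact enumeration of all placements instead.
* **TNS = SS·ANC if p ≤ 0.05 and ANC > 0, else 0**, clamped to [0, 1].
  Negative-ANC windows score 0 because the score is defined on [0, 1].

The implementation computes a gene × gene correlation matrix once (Spearman =
Pearson on ranks) and builds window pair-sums incrementally in k, so a full
run (2,000 genes, windows of 2–10, 1,000 permutations) takes a few seconds.

Run-based neighborhoods (for designs with too few replicates per tissue to
correlate) are maximal runs of ≥ 2 adjacent genes expressed in all replicates
of a tissue; "isolated" genes are expressed genes whose flanking probed genes
are all unexpressed (single flank at chromosome ends). A neighborhood is
"shared" with a second tissue when all its genes are expressed there. The
membership permutation test shuffles the expressed-flag vector across genome
positions and tests the in-run gene count (upper tail) and the isolated count
(lower tail).

## Chromatin domain scores

Island mass over a region is Σ height × overlap width; partial overlaps
contribute only the clipped width — the one convention that makes mass
additive over a partition of the region. CADR uses the two active marks
(H3K4me2 + H3K36me3), CSDR the silencing mark (H3K27me3), both as
tissue1/tissue2 ratios with a symmetric pseudomass `eps` (default 1.0
score·bp) in numerator and denominator: regions with no islands in either
tissue score exactly 1 (DS = 0), and log ratios stay finite. DS =
log2(CADR+1) − log2(CSDR+1); base 2 is the default (configurable) — with
realistic island masses it yields DS magnitudes up to ~±20 and makes a
threshold of 8 on log2(CADR) correspond to a ~256-fold mass ratio.

Classifications use strict inequalities exactly as stated: a gene is uniquely
active when log2(CADR) > 8 and log2(CSDR) ≤ 8, uniquely silenced in the
mirror case, inconsistent when both exceed 8, shared otherwise. Pair
classification at band t = 2: a gene is active (DS > t), silent (DS < −t) or
neutral; a pair is active/silent when both genes are, discordant when one is
active and one silent, concordant otherwise. The active-gene partition by
best TNS (> 0.4 in neighborhoods, < 0.01 outside) reads its thresholds as the
open intervals they are; genes sitting exactly on a threshold are counted in
a separate `boundary` bucket rather than silently assigned.

## The island caller and the gap scan

The caller is deliberately simplified: fixed 200-bp windows (about a
nucleosome plus linker), a single genome-wide Poisson background rate λ₀ =
total tags × W / effective genome length (an input library, when provided,
only rescales λ₀), eligibility when the Poisson upper tail beats a threshold,
and merging of eligible windows separated by at most the gap. There is no
control-library window testing, redundancy filtering, fragment-shift model or
E-value machinery; the pipeline's main path consumes externally produced
island files, and this module exists to exercise the gap-size scan end to
end.

`call_islands` itself is the pure merge: an island's score is the sum of its
eligible windows' scores (−ln Poisson tail). That sum is invariant under
merging, so a scan over gap sizes needs two further ingredients, both applied
in `gap_scan` only:

1. a **significance floor** (default 40 nats): only islands clearing it count
   toward the aggregate — isolated background windows and small fragments of
   a gappy domain fall below it;
2. a **gap penalty** of −ln(p_thresh) per bridged ineligible window: a
   background window spanned by an island counts against it exactly as much
   as the weakest admissible evidence counts for it.

Under these rules, widening the gap raises the aggregate only while it fuses
sub-floor fragments of genuinely broad domains into islands that clear the
floor, and lowers it once it merely bridges background — giving the scan an
interior maximum at the domain's internal dropout scale. Punctate marks peak
at the smallest gap; broad, internally gappy marks at a larger one. The
penalty must not be smaller: with a mild penalty (e.g. the expected
background window score), bridging toward an isolated eligible background
window is profitable and the argmax degenerates to the largest gap scanned.
The default eligibility threshold is 1e-4; at looser thresholds
background-eligible windows become dense enough (≈5 per 10⁴ windows at 0.01)
that such absorptions dominate the scan's tail. Ties in the scan break to the
smallest gap (parsimony).

## Group statistics

Distribution comparisons wrap the Wilcoxon rank-sum test with continuity
correction (Mann–Whitney U) and the two-sample Kolmogorov–Smirnov test,
two-sided by default with one-sided selectable; significance calls are left
to the caller. The hub test is a 2×2 chi-square on hub status (≥ 10 known
protein interactions by default) × gene set, without Yates correction by
default (both choices exposed). Differential-regulation classes are consumed
as a label table; calling them is out of scope.

## Synthetic data: what it emulates, and what it does not

Defaults are desk-scale: 2,000 genes on 4 chromosomes (exponential gene
lengths, mean 15 kb, and intergenic gaps, mean 60 kb), a 40-array timecourse
design (one tissue, 10 timepoints × 4 replicates) or an atlas-style design
(n tissues × 2 replicates), 10 comparison genomes, everything deterministic
given a seed, with the planted truth always emitted alongside.

* **Planted neighborhoods** (default 20, of 3–5 genes) share a per-sample
  latent factor with weight √ANC_target, so pairwise Pearson correlation
  equals the target (Spearman runs ≈ 0.015 lower at 0.8 — within the
  tolerance the recovery analyses use). Plants never abut (one guard gene on
  each side).
* **Distance decay** corr(d) = c·exp(−d/τ) (defaults c = 0.2, τ = 300 kb,
  weak correlations of the magnitude seen in real tissue panels) is realized
  by a chromosome-local AR process over gene starts, one independent field
  per sample.
* **Detection calls** threshold the simulated log2 value, with a narrow
  Marginal band; the expressed-state shift (+5 over a baseline of N(6, 0.7²),
  threshold 8) makes expressed genes Present in all replicates ~95% of the
  time, and the expressed fraction per tissue is set to ~28% — matching the
  ambient rate in real two-tissue comparisons where ~72% of genes are
  expressed in neither tissue. Expressed states are spatially autocorrelated
  so runs of expressed genes occur, and planted neighborhoods are always
  expressed.
* **Synteny** fragments the reference order with Bernoulli breakpoints per
  adjacency (rate 0.02) and drops genes at 0.05 per genome. Planted
  neighborhoods are protected from breakage and dropout in their first
  `syntenic_genomes` genomes and deliberately broken in the rest, so their
  SS is exact by construction.
* **Islands**: planted active domains carry H3K4me2+H3K36me3 islands, planted
  silenced domains broad H3K27me3 blocks, in one tissue only; domain margins
  stop short of flanking genes so a planted domain never contaminates a
  background gene. Background islands are placed at identical positions in
  both tissues with ±10% height jitter — encoding the empirical finding that
  chromatin state is mostly shared between tissues. Background is excluded
  from planted domains.
* **Tags**: uniform placement at a high rate inside domains (with optional
  dropout holes for broad marks) and a low rate outside.

What the generator does **not** model: probe effects and normalization
artifacts of real microarrays, tissue-specific variance structure,
read-level sequencing error, mappability, copy-number effects, and any
dependence between expression and chromatin plants (they are planted
independently). Passing recovery tests therefore demonstrates that the
pipeline's inference is correct under its own assumptions — planted signal
in, planted signal out — not that those assumptions hold in any particular
real dataset.

## Numerical conventions

Undefined correlations and unscorable windows are missing (NaN), never zero.
Permutation p-values use the plus-one estimator; exact enumeration is used
where the state space is tiny. The pipeline runner derives all randomness
from one config seed and stamps every output with the tool version and a
config hash, so equal configs produce byte-identical results. Problem sizes
in the shipped analyses (2,000 genes, 40 samples, 1,000 permutations, 10-Mb
tag genomes) are the generator defaults and complete in seconds on one core.

## Known limitations

The overlapping-transcript rule and the choice of correlation method for ANC
are declared substitutes where the upstream conventions are not fully
specified; both are configurable. The permutation null conditions on window
size but pools across chromosomes, which assumes exchangeability of profiles
genome-wide. The island caller's operating point (eligibility threshold,
floor, penalty) is a self-consistent simplified model, not a SICER
re-implementation, and its absolute chosen gaps are not comparable to
E-value-controlled SICER runs — only the ordering across marks is
meaningful. CADR/CSDR inherit whatever semantics the island "score" column
carries (read counts vs fold enrichment); the package treats it as given.
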
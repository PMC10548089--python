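# Methods

## Scope and model of the analysis

`cnidomir` re-implements, as a tested and reusable pipeline, the
computational core of a morphant transcriptomics study in a cnidarian:
a miRNA expressed in stinging cells (cnidocytes) is knocked down, bulk
RNA-seq is analysed for differentially expressed genes (DEGs), and the
DEG list is interrogated for cnidocyte specificity against (i) an
independently derived cnidocyte-enriched gene catalogue and (ii)
single-cell cluster marker sets, using permutation set-overlap tests.
A plant-style high-complementarity scanner predicts miRNA target
sites, and stem-loop qPCR assays are quantified by 2^-ddCt.

Upstream steps (read trimming, mapping, count quantification, the
internals of the DE methods, single-cell clustering and marker
calling) are consumed as tables, never recomputed. The deposited data
of the original experiments are not required anywhere: the
`synthetic_data` module generates every input with planted ground
truth, and all tests and the acceptance script run against those.

## Background filter and DEG definition

The background universe is built from the raw count matrix: CPM[g, l]
= counts[g, l] x 1e6 / library total[l], and a gene is removed iff its
CPM falls below `cpm_threshold` (default 1) in at least
`cpm_min_libraries` (default 2) libraries. The "at least two
libraries" rule is applied over all libraries pooled across
conditions; the parameter is configurable because the source
description names no per-condition grouping.

A gene is a DEG iff in *every* supplied DE method table (two by
default) the method's adjusted p is strictly below the FDR threshold
(0.05) and |log2 fold change| is at least log2 of the fold-change
threshold (2, i.e. |log2FC| >= 1, inclusive and two-sided), with
concordant fold-change direction across methods. Strict-vs-inclusive
mirrors the printed symbols "FDR < 0.05" and "fold change >= 2".
Genes passing both thresholds with discordant signs are excluded and
logged rather than raising (intersection semantics); genes absent
from any table are not DEGs; NA adjusted p counts as 1 with a warning.
The `benjamini_hochberg` helper (statsmodels' step-up implementation
behind a validated surface) exists only for synthetic tables — real DE
tables carry their own FDR.

## Permutation set-overlap enrichment

Given query Q (the DEGs), target T (e.g. the cnidocyte catalogue) and
background U, each of R (default 10,000) replicates draws |Q ∩ U|
genes uniformly **without replacement** from U and records the overlap
with T ∩ U. Query genes outside the background are dropped with a
warning; the target is intersected with the background; the observed
query is not injected into the null ensemble. Sampling without
replacement makes the null exactly hypergeometric:

    X ~ Hypergeom(B = |U|, K = |T ∩ U|, n = |Q ∩ U|),
    E[X] = nK/B,  P[X >= x] computed via scipy's stable tail.

This closed form is reported alongside as an oracle and enforced by
tests (exact integer combinatorics for every feasible configuration of
backgrounds up to 25 genes, literal subset enumeration up to 10, and
total-variation < 0.02 against a 1e5-replicate permutation ensemble).
Two empirical p-values are reported: `p_raw` = #{null >= x}/R (the
convention under which a never-exceeded observation prints "p = 0")
and `p_pseudo` = (#{null >= x} + 1)/(R + 1), which is recommended
because a true permutation p cannot be zero. The null histogram is
integer-binned with no smoothing. Only the one-sided "greater"
alternative is meaningful for enrichment; "less" exists behind a flag.

## Single-cell cluster distribution

The marker catalogue is a (gene, cluster) table; cluster ids are
opaque labels and "clusters 1-2 are cnidocytes" is configuration, not
code. A DEG that is a marker of several clusters contributes to each
cluster's count but once to the distinct-gene totals, keeping
fractions of the form 110/168 well-defined. When no DEG overlaps any
marker the focal fraction is flagged undefined (None), never reported
as 0. The focal-cluster enrichment test delegates to the permutation
machinery with target = union of focal-cluster markers.

## miRNA target scanning

The scanner defines a precise contract for the scoring scheme implied
by the published parameter set (maximum expectation 2, G:U penalty
0.5, seed weight 1.5, at most 2 seed mismatches, other mismatches 1,
gap open 2, gap extend 0.5, HSP size 19, seed region miRNA positions
2-13); bit-compatibility with any web service is not claimed. Per
aligned miRNA position (5'->3', 1-based): Watson-Crick pair 0, G:U
0.5, other mismatch 1; a gap run costs 2 for its first column and 0.5
for each further column; every penalty in the seed is multiplied by
1.5. The expectation is the sum. A site is emitted iff expectation <=
2 (boundary inclusive), seed mismatches <= 2 (G:U and gap columns in
the seed count toward the cap), and the number of paired columns is at
least the HSP size.

Search: for each window the optimal placement among the ungapped
alignment and all single-run gapped alignments with at most
`max_gaps` (2) total gap positions, gaps forbidden opposite the first
and last miRNA positions (standard duplex geometry). This is exact
under those constraints and is implemented with diagonal prefix sums,
vectorized over all window positions. A gap column in the miRNA row
(target bulge) is weighted by the next miRNA position to be aligned;
a gap in the target row (miRNA bulge) by its own unpaired miRNA
position — the convention under which a one-nucleotide non-seed bulge
scores exactly gap_open = 2.0, the acceptance boundary. Overlapping
candidate placements are resolved by keeping the locally
minimal-expectation placement, ties broken leftmost; ordering is fully
deterministic. T and U are interchangeable on input; duplexes are
printed as RNA, miRNA 3'->5' over the target 5'->3'.

## qPCR quantification and group comparison

Technical replicates are averaged first; dCt per biological replicate
is Ct(target) - Ct(reference); ddCt anchors to the **mean** control
dCt (the standard Livak convention — per-pair anchoring is not used);
RQ = 2^-ddCt with amplification efficiency fixed at 2. Mean anchoring
makes the *geometric* mean of control RQ exactly 1; the arithmetic
mean and SD (what bar plots show) are reported alongside. The
two-group comparison is the classical two-sided t test, computed
closed-form — equal-variance Student by default (matching how such
assays are reported), Welch by flag — and cross-checked against
scipy's implementation to 1e-6 in tests. Zero variance in both groups
degenerates to p = 1 (equal means) or a flagged p = 0.

## Synthetic data: what it emulates, and what it does not

* **Counts**: negative binomial with mean mu and dispersion alpha
  (var = mu + alpha mu^2; defaults mu = 150, alpha = 0.25, 6 libraries
  = 3 + 3), identical across libraries under the null. A chosen gene
  fraction (default 0.1) is forced to fail the CPM rule by zeroed
  libraries; the rest are floored to pass it, and the construction is
  verified against the filter before returning. No library-size
  imbalance, batch effects or condition-dependent expression are
  simulated — the pipeline never re-estimates DE, so the filter truth
  is the only property that matters.
* **Enrichment geometry**: target (size K) and query (size n) sets
  with overlap planted *exactly* at x, otherwise uniform. The
  study-scale configuration used in the analysis scripts is B =
  22,500, K = 2,615, n = 944, x = 268; the study's true post-filter
  background size is unpublished, so B is a free parameter set to a
  realistic transcriptome-scale value and never asserted.
* **Markers**: 12 clusters totalling 2,168 genes (defaults), each
  marker unique to one cluster so fractions are unambiguous; consumers
  still tolerate multi-cluster markers.
* **Transcripts**: each planted site class fixes its expectation by
  construction — perfect 0, one non-seed G:U 0.5, one seed mismatch
  1.5 (self-pairing, never Watson-Crick nor wobble), one-nucleotide
  non-seed target bulge 2.0, decoy 4.5 (three seed mismatches, never
  emitted). Flanks are rejection-sampled (cap 1,000 attempts, then an
  explicit error) until the scanner reports exactly the planted
  non-decoy sites.
* **DE tables**: planted DEGs pass both methods; non-DEGs cover the
  failure taxonomy (significance only, fold change only, one method
  only, discordant signs, padj exactly at the FDR cutoff, missing from
  one table), with a slice of DEGs exactly at |log2FC| = 1 so both
  threshold boundaries are exercised.
* **qPCR**: Gaussian Ct noise per technical measurement; at zero noise
  the planted fold change is recovered exactly, by construction of the
  ddCt identity.

Passing tests on these generators shows the *logic* is exact and the
statistics calibrated; it does not validate behaviour under real-data
pathologies (id mismatches across catalogues, library imbalance,
marker duplication, partial FASTA corruption) beyond the specific
error contracts tested.

## Numerical and design choices

* Gene identifiers are opaque, case-sensitive strings; catalogue
  dialects are reconciled, if needed, by a caller-supplied two-column
  mapping file (`read_mapping`), never by guessing.
* One process-wide seed fans out into named per-stage child streams
  (`derive_rng(seed, stage)`), so runs are byte-reproducible and
  stages are decoupled.
* Permutation sampling is vectorized by permuting a 0/1 target
  indicator row-wise, chunked to bound memory; the small-universe
  validation sweep shares one permutation ensemble per background size
  across all (K, n), which is what makes an exhaustive sweep
  affordable on one CPU.
* Hypergeometric tails come from scipy's log-space implementation and
  are stable to B = 1e6; out-of-support observations resolve to 0/1 by
  convention, logged.
* Floating comparisons against the expectation cutoff use a 1e-9
  slack so a site at exactly 2.0 is always emitted.
* Problem sizes in the test and acceptance runs (background 5,000 with
  K = 650, n = 472 and R = 999 for calibration; 500 null and 200
  enriched datasets; 50 scanner seeds; 100 filter/DEG universes;
  backgrounds up to 25 for the oracle sweep) are the package's chosen
  desk-scale study conditions: large enough that p-value discreteness
  does not dominate the calibration statistics, small enough to run
  routinely.

## Known limitations

* The scanner's gap model (single gap run, <= 2 gap positions, no
  terminal gaps) is a deliberate re-specification; duplexes with more
  exotic geometry are out of contract.
* No expression- or length-matched null for the enrichment test — the
  null is uniform over the background, as in the analysis it
  re-implements.
* Single reference gene only in qPCR; no efficiency calibration.
* The headline numbers of the original study (944 DEGs, 805 down, 268
  overlap, null means 109.54 and 18.32, 110/168 = 65.4%) depend on
  deposited accessions and an unpublished background size; they appear
  here only as documentation examples and as the geometry of the
  synthetic configurations, not as recomputed results.
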
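# cnidomir

Cnidocyte miRNA morphant transcriptomics: a tested, reusable
implementation of the analysis chain behind a miRNA knockdown study in
a cnidarian — background filtering and DEG definition, permutation
set-overlap enrichment against cnidocyte gene sets, distribution of
DEGs over single-cell cluster markers, plant-style
high-complementarity miRNA target scanning, and stem-loop qPCR
quantification — exercisable entirely on synthetic data with planted
ground truth.

It is written for people who analyse knockdown RNA-seq in non-model
organisms and want the statistics of "is my DEG list enriched for
cell-type X genes?" to be explicit, seeded and testable, rather than
buried in one-off scripts.

## The statistics at the core

**DEG definition.** A gene is differentially expressed iff *both* DE
method tables report FDR < 0.05 and |log2FC| ≥ 1 (fold change ≥ 2)
with concordant direction. The background universe keeps genes with
CPM ≥ 1 in all but at most one library (a gene below 1 CPM in ≥ 2
libraries is removed).

**Permutation overlap test.** For query Q (n genes), target T (K
genes) and background U (B genes), each of R = 10,000 replicates
draws n genes uniformly without replacement from U and counts the
overlap with T. Empirical p-values are reported raw
(#{null ≥ x}/R) and with pseudocount ((#{null ≥ x}+1)/(R+1)).
Because the null is exactly hypergeometric,

    X ~ Hypergeom(B, K, n),   E[X] = nK/B,

the closed-form tail P[X ≥ x] is computed alongside as an oracle, and
the test suite enforces agreement (exact enumeration for small B,
total variation < 0.02 at R = 1e5).

**Target scanning.** A miRNA is aligned antiparallel against every
transcript window; the duplex *expectation* penalty sums Watson–Crick
0, G:U 0.5, mismatch 1, gap open/extend 2/0.5, with every penalty in
the seed (miRNA positions 2–13) weighted 1.5. Sites with expectation
≤ 2, ≤ 2 seed mismatches and ≥ 19 aligned positions are reported.

**qPCR.** Relative quantity per biological replicate is 2^−ΔΔCt with
technical replicates averaged first and ΔΔCt anchored to the mean
control ΔCt; group comparisons use the classical two-sided Student
(or Welch) t test.

## Worked example

The numbered scripts under `analysis/` run the whole study on
synthetic data and write their tables under `results/`:

```
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_background_and_degs.py
python analysis/03_catalogue_enrichment.py --seed 1
python analysis/04_cluster_overlap.py --seed 1
python analysis/05_scan_targets.py
python analysis/06_qpcr_quantification.py
```

which prints, among other lines:

```
background: retained 1760/2000 genes; matches planted truth: True
DEGs: 120 (18 up, 102 down), 3 discordant excluded; matches planted truth: True
observed overlap 268 of 944 DEGs; null mean 109.74 (closed-form expectation 109.71);
    null max 146; p_raw 0, p_pseudo 9.999e-05, hypergeometric p 8.93e-47
121 DEGs overlap the marker catalogue; 82 in focal clusters ['1', '2'] (67.8%);
    enrichment null mean 31.42, p_pseudo 9.999e-05
4 sites emitted at expectation <= 2.0; 4/4 planted sites recovered at their exact class scores
planted fold change 0.25; recovered treatment mean RQ 0.1814 (sd 0.0217) at Ct noise SD 0.3
```

Reading these: the CPM filter and the DEG intersection reproduce the
generator's planted truth exactly; a planted 268-gene overlap between
a 944-gene DEG list and a 2,615-gene cnidocyte catalogue over a
22,500-gene background sits far above the permutation null (mean
≈ 110, maximum 146 over 10,000 random lists), so the raw empirical p
is 0 and the pseudocount p is 1/(R+1); the DEGs concentrate in the
two cnidocyte marker clusters; the scanner recovers every planted
site at its constructed expectation score (0 / 0.5 / 1.5 / 2.0) and
rejects the decoys; and the 2^−ΔΔCt analysis recovers a planted
4-fold knockdown up to Ct noise.

The same stages are available as CLI subcommands
(`cnidomir simulate|filter-background|call-degs|enrich|cluster-overlap|scan-targets|qpcr`,
each with `--config/--seed/--out-dir`) and, of course, as library
functions — see `docs/methods.md` for the full model description and
design decisions.

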
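# thsspipe

Differential Tn5-hypersensitive-site (THSS) analysis for two-condition,
multi-stage ATAC-seq + RNA-seq designs — built around the comparison of
Huntington's-disease (HD) and wild-type (WT) cells across the stages of
astrocyte differentiation (pluripotent stem cells → neural progenitors →
day 3 → astrocytes), and validated end-to-end on synthetic data with
planted ground truth.

## Who this is for

Epigenomics analysts who have, per condition and stage: ATAC-seq fragment
intervals (BED), replicate peak calls (BED with summit offsets), a genome
(FASTA), gene models (GTF subset), transcription-factor motifs (MEME
minimal format), a cuffdiff-style differential-expression table, gene sets
(GMT) and candidate enhancer regions (BED) — and who want differential
accessibility, motif enrichment, and expression integration with every
threshold explicit and testable.

## The method

**Fragment preprocessing.** Fragments are Tn5-offset corrected (+4 bp on
the plus-strand cut, −5 bp on the minus-strand cut) and classed by length:
sub-nucleosomal (< 125 bp, the THSS signal) and mononucleosome
(171–254 bp, used for promoter occupancy).

**Differential THSS calling (MA normalization).** For HD and WT pooled
counts x₁, x₂ in each peak,

    M = log2((x₁+½)/(x₂+½)),   A = ½·log2((x₁+½)(x₂+½))

A robust line M = a + b·A is fitted over peaks common to both samples
(Huber start, Tukey-bisquare refinement) and the WT counts are rescaled
by 2^(a + b·A), removing depth and intensity-dependent bias. Each peak is
then tested with a two-sided exact binomial test on the rounded normalized
counts (null: each fragment equally likely from either condition) and
BH-adjusted. A peak is called differential iff

    logCPM > 1  AND  ( q < 0.01  OR  ( |logFC| > 3  AND  p < 0.01 ) )

where logCPM is log2 of the mean of the two conditions' counts-per-million.
Peaks on the excluded chromosomes (chr2a, chr2b by default) are dropped.
Peaks within ±500 bp of any TSS are promoter-proximal, the rest distal.

**Motif enrichment.** Windows of ±200 bp around each peak summit are
scanned on both strands with log-odds PWM scores; match p-values come from
the exact discretized null score distribution (positionwise convolution,
1/1000-bit grid). Only the most significant motif per peak is kept. For
each motif X, direction (HD-up or WT-up) and context (proximal/distal),
the 2×2 table

    N11 = direction peaks whose best motif is X   N12 = … another motif
    N21 = all condition peaks with best motif X   N22 = … another motif

is tested with a two-sided Fisher exact test (rows deliberately nested;
raw p-values, no multiple-test correction — motif p-values are strongly
dependent across related factors).

**Integration.** Expression heatmap values are floored log-ratios:
log2((FPKM_HD+10⁻⁴)/(FPKM_WT+10⁻⁴)), set to 0 when both FPKM < 1. DE-gene
versus gene-set overlap uses the analogous nested Fisher table. Each DE
gene is associated with its nearest differential peak (flagged within
250 kb), and differential distal peaks are intersected with candidate
enhancers with both directed counts reported.

**Synthetic data.** `thsspipe.synth` generates a seeded dataset that
emulates the study design — 2 conditions × 4 stages × 2 replicates, a
condition-level depth bias, ~10 % differential peaks at |log2FC| = 4, a
motif planted into 80 % of HD-up summit windows, stage-patterned DE genes
(including an NPC-down/astrocyte-up inverse pattern) — with truth tables
for recovery scoring.

## Worked example

```python
from thsspipe.synth import SyntheticConfig, generate_dataset, evaluate_recovery
from thsspipe.pipeline import config_for_dataset, run_pipeline

ds = generate_dataset(SyntheticConfig(seed=1))
ds.write("scratch/demo")
report = run_pipeline(config_for_dataset("scratch/demo", "scratch/demo_out"))

print(report.differential_summary[
    ["stage", "total_differential", "enriched", "enriched_pct"]])
print(evaluate_recovery(ds, report))
```

prints (seed 1):

```
       stage  total_differential  enriched  enriched_pct
0        PSC                  96        48          50.0
1        NPC                  96        48          50.0
2       day3                  96        48          50.0
3  astrocyte                  95        48          50.5
{'sensitivity': 0.9973958333333334, 'fdr': 0.0, 'n_truth_differential': 96,
 'n_selected': 383, 'planted_motif_worst_rank': 1,
 'planted_geneset_p': 2.3209042562699226e-20}
```

Per stage, ~96 of the 976 peaks are called differential — the planted 10 %
(48 up, 48 down), recovered at 99.7 % sensitivity with no false calls; the
planted motif ranks first by Fisher p among HD-up distal peaks at every
stage, and the planted DE gene set overlaps the called DE genes at
p ≈ 2×10⁻²⁰. The same run writes `differential_<stage>.tsv`,
`motif_enrichment.tsv`, `overlap_tests.tsv`, `associations.tsv`,
`logratio_matrix.tsv` and `qc.tsv` under the output directory.

The same pipeline is available from the shell:

```
thsspipe generate --seed 1 --out-dir demo_data
thsspipe run-all --config run.yaml
```

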
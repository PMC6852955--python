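# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the model behind the synthetic-data generator, and the known
limits of both.

## Coordinates and preprocessing

All internal coordinates are 0-based half-open (BED convention); GTF-style
1-based inclusive input is converted on read. Fragment preprocessing
applies the Tn5 insertion-site offset (+4 bp to the plus-strand cut, −5 bp
to the minus-strand cut); fragments whose shifted interval degenerates
(start ≥ end, i.e. raw length ≤ 9 bp) are dropped and tallied in QC rather
than treated as fatal. Size classes are: non-nucleosomal (< 125 bp, the
Tn5-hypersensitive signal used for peak analysis), mononucleosome
(171–254 bp, used for promoter occupancy), other. The boundary values are
inclusive exactly as written: 124 is non-nucleosomal, 125 is not; 171 and
254 are mononucleosome, 170 and 255 are not.

Interval merging treats touching intervals (gap 0) as overlapping,
matching common merge-tool defaults; a `min_gap` parameter widens this.
Proximity to a TSS (±500 bp, any transcript's TSS counts) is measured by
edge overlap with the closed TSS window — whether the original definition
measured from the region edge or its summit is not determinable from the
published description, so edge overlap is used and stated here as an
assumption. Nearest-feature ties are broken deterministically: smaller
absolute distance, then upstream over downstream, then smaller target
start.

## Differential accessibility model

The two pooled samples (test condition HD = sample 1, reference WT =
sample 2) are compared per peak. With pseudocounted counts, M =
log2((x₁+½)/(x₂+½)) and A = ½·log2((x₁+½)(x₂+½)).

**Normalization.** A linear M-on-A trend is estimated over *common* peaks
— peaks called in both samples (≥ 1 bp overlap or summits within 250 bp,
configurable) — and removed by rescaling sample 2: x₂′ = x₂·2^(a+b·A).
The fit is an iteratively reweighted M-estimate: a Huber pass for a stable
start, refined with a redescending Tukey bisquare (statsmodels RLM, 50
iterations, tolerance 1e−8). The bisquare matters: truly differential
peaks that survive into the common set are gross M outliers sitting
asymmetrically in M-A space, and a bounded-influence estimator like Huber
alone lets them tilt the line measurably (a slope bias of ~0.4 at 10 %
planted differential peaks in pilot simulations), whereas the redescending
weight zeroes them out. Peaks with a zero count in either sample are
excluded from the fit but still normalized and tested.

**Test.** Each peak's normalized counts are rounded (half-even, for
determinism) and tested with a two-sided exact binomial test of k₁
successes in k₁+k₂ trials at probability ½ — the conditional test of equal
Poisson rates. Both counts zero gives p = 1 by convention. q-values are
Benjamini–Hochberg across all peaks of the comparison.

**Selection.** A peak is differential iff logCPM > 1 AND (q < 0.01 OR
(|logFC| > 3 AND p < 0.01)), with logCPM the log2 of the mean of the two
conditions' CPM (mean of CPMs, not mean of logs — the edgeR-style
convention; an assumption, since "averaged" is ambiguous) computed from
the raw counts (CPM already corrects depth), and logFC the
post-normalization M. Differential peaks on the excluded chromosomes
(chr2a/chr2b by default — duplicated-assembly chromosomes in the macaque
reference this workflow was built around) are dropped. Direction follows
the sign of logFC (HD_up / HD_down).

The exact binomial test models *counting* noise only. It is exactly
calibrated when counts are Poisson about a common mean and becomes
anti-conservative under extra-Poisson (replicate-level biological)
dispersion, which pooling replicates before testing cannot capture. This
is a real limitation of the normalize-then-binomial-test family of
methods, inherited deliberately; see the generator section for how the
validation treats it.

**Promoter occupancy** runs the identical count → normalize → test →
select machinery over 2-kb TSS-centred windows using mononucleosome
fragments. Replicate QC reports the Pearson correlation of log2(count+1)
across the analysis peak set (NA for constant vectors).

## Motif analysis

Scanning windows are ±200 bp around each peak summit. PWM rows off unity
by ≤ 1e−3 are renormalized, worse is an error. Scores are log2-odds
against a 0-order background (the MEME file's, uniform when absent) with a
1 % uniform pseudo-probability mixed into the motif columns so impossible
bases stay finite. The null distribution of the score of a random
background word is computed exactly by positionwise convolution on a
1/1000-bit integer grid, giving FIMO-comparable match p-values; both
strands are scanned, windows containing N are skipped, and the default
match threshold is p ≤ 1e−4.

Per peak only the most significant match (any motif) is kept, with a fixed
tie order (higher score, leftmost offset, plus strand, motif id);
deduplication happens once per peak, before the proximal/distal split.
For each motif × direction × context, the contingency table counts best
hits among that direction's differential peaks (N11/N12) against best hits
among *all* peaks called in that condition (N21/N22) — the rows are nested
by construction and the table is tested as-is with a two-sided Fisher
exact test; it is not reshaped into a disjoint 2×2. Raw p-values are
reported with no multiple-test correction: p-values of related motifs are
strongly dependent, violating the weak-dependence assumptions of FDR
procedures, so results with p < 0.05 are only flagged, not filtered.

## Integration

Expression log-ratios are log2((FPKM_HD+0.0001)/(FPKM_WT+0.0001)), set to
exactly 0 when both FPKM < 1; replicate FPKMs are pooled by arithmetic
mean before the ratio, and missing (gene, stage) pairs impute (0, 0).
Gene-set overlap uses the same nested-row Fisher construction with the
annotated-gene universe. DE calls default to q < 0.05 with the stricter
q < 0.01 available as a setting (both cutoffs appear in the source
material for different analyses; neither is asserted as canonical).
Nearest-peak association measures peak-edge to TSS-point distance and
flags |distance| ≤ 250 kb. Enhancer overlap reports both directed counts
(enhancers hit by ≥ 1 differential distal peak, and peaks hitting ≥ 1
enhancer) because the two differ whenever regions chain or nest, plus the
intragenic fraction of hit enhancers. Heatmap row order is deterministic
average-linkage on Euclidean distances.

## Synthetic data generator

The generator emulates a 2-condition × 4-stage × 2-replicate design at
desk scale: 2 × 1 Mb uniform-base chromosomes plus chr2a/chr2b decoys
(100 kb each, always planted differential, exercising the exclusion rule),
200 non-overlapping genes, ~1000 peaks of 400 bp (20 % at TSSs), 20 sharp
PWMs (dominant base 0.85, ~1.4 bits/position). Study conditions are the
defaults: 10 % of main-chromosome peaks differential at |log2FC| = 4 (half
per direction, fold applied to the HD mean), a 2× WT depth bias that the
normalization must remove, per-replicate peak means of 50 (pooling to
~100) with lognormal (σ = 0.4) peak-to-peak spread, the first motif's
consensus written into 80 % of HD-up summit windows versus 10 % background
(other motifs 10 % everywhere, random strand, non-overlapping positions),
and 15 % DE genes at |Δlog2| = 3 under four stage patterns — all-up,
all-down, late-up, and an inverse pattern (down in NPCs, up in
astrocytes) mirroring the cell-cycle/E2F-style reversal the integrative
analysis is meant to expose.

Two generator choices deserve justification:

- **Counting noise is negative binomial with default dispersion 0 (the
  Poisson limit), variance μ + φμ².** The pipeline pools replicates and
  its test models counting noise only, so the matched validation
  condition is Poisson; the dispersion knob exists to study robustness,
  and raising it makes the test anti-conservative exactly as it would on
  overdispersed real data. Passing recovery tests therefore demonstrate
  correctness of the machinery under the test's own noise model, not
  robustness to biological replicate variance.
- **Expression p-values are a two-sample z-test on log2 replicate means
  with the replicate noise (σ = 0.25 log2 units) treated as known.** With
  duplicate samples a per-gene variance estimate has one degree of
  freedom and essentially no power; count-model DE tools achieve their
  power by borrowing variance strength across genes, and the known-σ
  z-test is the simplest stand-in with the same character. It is exactly
  calibrated under the generator's null.

Replicate peak calls are jittered (±10 bp) copies of the true peaks,
called per replicate at 97 %, and *condition-gated*: a peak whose expected
replicate count in a condition is below 20 is not callable there, the way
a peak caller cannot call what it cannot see. This is what makes strongly
differential peaks condition-specific and keeps them out of the
common-peak normalization set.

All draws flow through one seeded generator; outputs are byte-identical
given the seed.

What the generator does *not* model — and what passing tests therefore do
not show about real data: sequence composition bias (uniform-base genome),
Tn5 insertion-sequence preference, replicate-level biological dispersion
(above), peak-width and shape heterogeneity, motif occurrences in
flanking/background sequence beyond the planted rates, GC-dependent
expression effects, and any read-level error process.

## Numerical choices and degenerate inputs

Counts use a +0.5 pseudocount inside logs; expression ratios use +0.0001.
Percentages in summary tables round half-up to one decimal; zero totals
render NA. Rounding of normalized counts for the binomial test is
half-even. The motif score grid is 1/1000 bit; a float score just past the
last achievable bin clamps to the best-word tail mass. Fisher tables with
a zero row sum return p = 1 with a warning. Fewer than two usable common
peaks fail normalization loudly, except the zero-fragment promoter
occupancy case, which returns an empty result. Hierarchical ordering of a
single row is the identity. The analysis pipeline draws no random numbers;
reports are byte-reproducible.

## Problem sizes used in validation

The standard validation dataset is the default configuration above
(~976 peaks after placement, 4 stages, ~230k fragments per stage and
condition); the recovery suite runs it once end-to-end. Null calibration
uses 5000 peaks at mean count 100. Oracle checks enumerate all words for
motif widths ≤ 6 and all fixed-margin tables at margins ≤ 30. These sizes
give the power the stated bounds need (pilot-run tuned, then frozen)
while keeping a full validation run in the minutes range on one CPU.

## Known limitations

Whether this MA-normalization + exact-binomial formulation matches the
internals of any specific published differential-peak tool cannot be
established from the method's prose description alone; validation
therefore rests on planted-truth recovery and calibration, not on
reproducing any published genome-scale count. The nested contingency
tables (motif and gene-set) are tested literally as defined, which makes
their p-values conservative relative to a disjoint-row design. FPKM-level
expression simulation sidesteps gene length and depth; the DE calling it
feeds is only as realistic as the known-σ z-test above.
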
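# Methods

## Overview

`sjkit` quantifies differential pre-mRNA splicing directly from splice-junction
read counts, without transcript assembly or read-level re-analysis. Per-sample
junction tables in the STAR `SJ.out.tab` dialect are merged over the union of
unique junction positions into one junctions × samples count matrix of
unique-mapping reads (multimapping reads are parsed but never counted). All
coordinates are 1-based closed intron coordinates: a junction is keyed by the
first and last intronic bases, so identity is exactly the tuple
(chrom, start, end, strand). Conversion to other conventions (BED) happens only
at the I/O boundary.

## Normalization

Between-sample scaling uses the trimmed mean of M-values (TMM). The reference
sample is the one whose 75th-percentile CPM, computed over rows nonzero in
that sample, lies closest to the across-sample mean of that quantity (ties go
to the lowest sample index). For each other sample, M (log2 CPM ratio) and A
(average log2 abundance) are computed over rows positive in both sample and
reference, 30% of each M tail and 5% of each A tail are trimmed, and the
scaling factor is 2 to the precision-weighted mean of the surviving M values,
with weights from the standard asymptotic (binomial) variance of M. Factors
are rescaled to geometric mean 1 after every call. When fewer than 10 rows
survive the double trim the untrimmed weighted mean is used (logged); a sample
sharing no nonzero rows with the reference gets factor 1 (logged). The
implementation was cross-checked against an independent loop-based
transcription of the definition (shipped in the test suite).

The downstream working scale is log2 counts-per-million with a prior count
(default 0.5) on TMM-effective library sizes:
`log2((y + prior) / (N_eff + 2·prior) · 1e6)`. This is a deliberate choice:
the deviation statistic below supplies its own variance moderation, so a full
precision-weight (voom-style) mean–variance fit is out of scope, and log-CPM
keeps every downstream quantity a simple difference of logs.

## Gene-level expression and the deviation call

A gene's expression is summarized from the canonical junctions (consecutive
exon gaps) of its *most abundant isoform*: for each transcript the abundance
proxy is the mean log-CPM over its matrix-present junctions averaged over all
samples; the argmax transcript is chosen once, across the whole study, so the
gene baseline cannot flip between the two arms of a contrast (ties go to the
lexicographically smallest transcript id). Gene expression per sample is the
mean log-CPM over the chosen transcript's junctions, and the gene log2 fold
change is the difference of condition means (condition B − condition A, with
condition order taken from the design).

A junction is differentially spliced when its own fold change deviates from
the gene-level change. The test statistic works on the per-sample residual
r = junction log-CPM − gene expression. The deviation delta is the difference
of condition means of r, which is algebraically identical to
(junction log2FC − gene log2FC) and is computed as that difference exactly.
The pooled within-condition variance of r (df = n_A + n_B − 2) is shrunk
toward a prior scale s0² (the median residual variance across tested
junctions) with prior df d0 = 4, an empirical-Bayes moderation in the limma
spirit but fully closed-form; the statistic is t with d0 + df degrees of
freedom, two-sided, with Benjamini–Hochberg FDR across all tested junctions.
Default call thresholds are FDR < 0.05 and |delta| ≥ 1 log2 unit; both are
parameters. Junctions are tested only when expressed (count ≥ 5 in at least
min(n_A, n_B) samples, configurable); junctions mapping to no gene or to
several genes are reported in an "unassigned" sidecar rather than silently
dropped. With one replicate per condition only delta is reported (p undefined).

Junction–gene assignment prefers exact annotated-junction identity (a junction
derived from exactly one gene's transcripts takes that gene); an unannotated
junction strictly inside exactly one strand-compatible gene span is assigned by
containment; strand-unknown junctions are assignable by containment only. Two
or more candidates at either stage yield "ambiguous" — the original analyses do
not state how multi-gene junctions were handled, so they are flagged, never
guessed.

## Event classification and PSI

Within a gene, a splice graph is built with donor/acceptor coordinates as
nodes and junctions as edges. Event definitions are structural:

* **SE** — two junctions flanking an annotated exon plus the skipping junction
  spanning the same outer coordinates.
* **A5SS / A3SS** — junction pairs sharing the acceptor (resp. donor)
  coordinate; the shorter intron (longer exonic form) is the inclusion form.
  Labels follow the forward-strand convention of the coordinates.
* **MXE** — two inclusion paths between the same outer donor/acceptor through
  two annotated exons that co-occur in no annotated transcript (mutual
  exclusivity is decided from annotation, not counts).

PSI per sample is (I1+I2)/(I1+I2+2S) for SE (skip reads are doubled because
the inclusion form is crossed by two junctions) and I/(I+S) otherwise, and is
undefined when the denominator is zero. The PSI difference between conditions
is tested by label permutation preserving group sizes: all distinct label
assignments are enumerated when there are at most 1000, otherwise Monte Carlo
with a mandatory seed and the (1 + exceedances)/(1 + draws) convention.
Significance requires BH FDR < 0.05 and |ΔPSI| > 0.1. Note the exact-test
granularity: a 3v3 design has only C(6,3) = 20 label splits, so p can never go
below 0.1 and FDR < 0.05 is unreachable at that size — effect-size ranking is
the meaningful readout for small designs. Retained introns are not called:
junction tables carry no intron-body coverage, so RI candidates would be
untestable and are out of scope.

## Two-isoform switch calls

For a gene with exactly two isoforms whose diagnostic junction sets (junctions
private to one isoform within the gene) are nonempty, the switch call pools
each isoform's diagnostic counts per condition:
prop_a = Σdiag_a / (Σdiag_a + Σdiag_b). The reported delta is condition B −
condition A of isoform a's share; the p-value uses the same label-permutation
machinery on per-sample shares. Because the two diagnostic sets may differ in
size (the glutaminase KGA isoform contributes four private junctions, GAC
one), the pooled share is not the isoform fraction itself; the between-
condition contrast is the signal. Genes with three or more diagnosable
isoforms are rejected with a pointer to pairwise calling.

## Companion statistics

* Spearman correlation: mid-ranks for ties; t approximation for n ≥ 10, exact
  enumeration of all pairings below; constant vectors yield NaN.
* Kaplan–Meier / log-rank (via lifelines): product-limit curves per group,
  two-group log-rank chi-square with 1 df; censoring at an event time follows
  the standard events-first convention. Expression stratification uses strict
  ">" for the high group (boundary values go low); published cutoffs are
  treated as given parameters, not recomputed optima.
* ΔΔCt: replicate-averaged ΔCt = target − reference per sample, baselined to
  the control-group mean, reported as 2^(−ΔΔCt); the control group's mean ΔΔCt
  is zero by construction.
* Gene-effect screening: essentiality filter keeps genes whose across-line
  mean score is strictly below −0.4 (missing values ignored); co-dependency
  correlates the query's effect profile with every gene pairwise-complete
  (Spearman or Pearson; minimum overlap 10 lines, configurable) with BH FDR.
* Over-representation: one-sided hypergeometric upper tail per category, BH
  FDR.
* Spectral-count enrichment: counts are divided by protein length and rescaled
  to preserve each sample's raw total, then the two-sample G-test
  G = 2(a′·ln(a′/e) + b′·ln(b′/e)), e = (a′+b′)/2, with pseudocount 0.5 by
  default (0·ln 0 := 0 when the pseudocount is 0), p from the chi-square(1)
  upper tail, BH FDR, and "enriched" requiring bait > control.
* Multiple testing is Benjamini–Hochberg everywhere, as the single exposed
  procedure.

## Synthetic data

The generator produces every input the pipeline consumes, as a deterministic
function of a config and a seed. A toy single-chromosome annotation tiles
genes with 10 kb gaps (an overlap mode plants overlapping spans for the
ambiguity path). Isoform counts per gene are drawn with probabilities
(0.5, 0.4, 0.1) for 1/2/3 isoforms. Single-isoform genes draw 3–10 exons;
multi-isoform genes draw 6–10, because a 3-exon cassette gene has *no* shared
junction — its gene baseline would consist entirely of isoform-diagnostic
junctions and the deviation readout would be degenerate by construction.
Two-isoform genes are either a cassette exon or an alternative-terminal-exon
pair patterned on glutaminase (shared 5′ exons, one terminal exon vs a short
distinct terminal run).

Expected junction counts are library size × gene weight (log-normal, σ = 1)
× condition DE factor × the summed proportions of the isoforms containing the
junction, with uniform junction usage within a transcript (an optional
log-normal jitter adds junction-level heterogeneity). Counts are negative
binomial with variance m + φ·m² (φ = 0.1 default); library sizes are
log-normal around 10⁶ with σ = 0.3; replicates default to 3 per condition.
Planted switches flip a symmetric proportion pair (0.5 ± δ/2) between
conditions, δ drawn from [0.3, 0.6] by default; planted DE genes multiply all
junctions by a factor of 2–4 in one condition (and therefore, correctly,
produce no deviation signal). Ground truth (per-gene proportions, DE factors,
switch flags, per-junction roles and expected counts) is returned for
parameter-recovery tests.

What the generator does *not* emulate: unannotated/novel junctions,
alignment artifacts, strand-unknown junction noise, gene-level correlated
biological noise (junction counts are conditionally independent given the
mean), 3′ coverage bias, and batch effects. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated count model, not
robustness to those real-data features.

## Calibration and power at the default study size

Null simulations (200 genes, 3v3, φ = 0.1) put the deviation test's type-I
error at its nominal 5% within binomial tolerance, and the G-test and
log-rank nulls behave likewise. Power is a different matter: with 3 replicates
per condition and φ = 0.1 the per-junction residual SD is ≈ 0.4 log2 units,
and BH across ~1400 junctions puts the effective per-junction significance
threshold near 10⁻³, so only deviations of roughly 1.7 log2 units or more are
reliably detectable. Planted switches with |Δproportion| in [0.4, 0.6]
produce diagnostic-junction deltas of 0.6–3.1 (median ≈ 1.7), of which about
half are recovered at FDR < 0.05 — with essentially no false discoveries and
with the switch *direction* recovered for all planted genes by the pooled
diagnostic-count call, which aggregates over junctions and is much better
powered than any single-junction test. Detecting the weaker half at this
design size requires more replicates, lower dispersion, or gene-level
aggregation; the per-junction sensitivity ceiling is a property of the test at
these conditions, not an implementation artifact.

Problem sizes used by the shipped tests and the acceptance script — 200-gene
studies with 3v3 replicates for calibration and recovery, 60 toy genes for
exhaustive event enumeration, 10⁴ draws for G-test calibration, 10³ trials
for the log-rank null — were chosen to make every check exhaustive or tightly
converged at interactive run times.

## Known limitations

* Intron retention is not called (no intron-body coverage in junction tables).
* A5SS/A3SS labels are coordinate-based (forward-strand convention).
* The deviation test conditions on the chosen "most abundant isoform"; genes
  whose dominant isoform is itself ambiguous get a noisier baseline.
* Exact permutation p-values are bounded below by the number of label splits;
  small designs cannot reach small FDRs.
* The spectral-count G-test assumes an equal-split null after size
  normalization; it does not model sample-specific capture efficiency beyond
  the total-count rescaling.
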
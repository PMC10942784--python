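# sjkit — splice-junction toolkit

`sjkit` detects differential pre-mRNA splicing directly from splice-junction
read counts, for studies that compare two genotypes or treatments (e.g. a
splicing-regulator knockdown against control) from standard aligner output.
It is aimed at computational biologists who have per-sample STAR
`SJ.out.tab` junction tables and a gene annotation, and want junction-level
splicing calls, event classification with inclusion levels (PSI), and
isoform-switch calls of the glutaminase GAC/KGA type — plus the cohort and
screening statistics that typically surround such an analysis (Kaplan–Meier
stratification, Spearman correlation, ΔΔCt, CRISPR co-dependency, and
spectral-count G-test enrichment for interactome data).

## The method

For samples *s* and junctions *j*, the unified matrix collects unique-mapping
read counts over the union of junction positions. After TMM normalization the
working scale is log2-CPM, `x_{js}`. A gene *g*'s expression is the mean
log-CPM over the canonical junctions of its most abundant isoform, `g_s`, and
a junction's splicing signal is the deviation of its fold change from the
gene's:

    delta_j = log2FC(x_j) − log2FC(g)     (condition B − condition A)

tested with a moderated t on the residual r_{js} = x_{js} − g_s:

    s̃_j² = (d₀·s₀² + df·s_j²) / (d₀ + df),   t_j = delta_j / (s̃_j·√(1/n_A+1/n_B))

with d₀ = 4, s₀² the median residual variance, df = n_A + n_B − 2, and BH FDR
across junctions. A junction is called at FDR < 0.05 and |delta| ≥ 1.
Splice-graph events (SE, A5SS, A3SS, MXE) get per-sample PSI — for a skipped
exon PSI = (I₁+I₂)/(I₁+I₂+2S) — and an exact label-permutation test of ΔPSI.
Two-isoform switches are called from isoform-diagnostic junction counts
pooled per condition. A synthetic-data module generates annotations and
negative-binomial junction counts with planted switches and DE genes, so the
whole pipeline is testable with no downloads.

## Worked example

```python
import sjkit

config = sjkit.SimConfig(seed=1, n_genes=100, n_switch=10, n_de=10)
result = sjkit.simulate_study(config)           # annotation + SJ counts + truth
matrix = result.matrix

factors = sjkit.tmm_factors(matrix)
logmat = sjkit.log_cpm(matrix, factors)
assignment = sjkit.assign_junctions_to_genes(matrix, result.models)
estimates = sjkit.estimate_gene_expression(matrix, logmat, result.models)
calls, _ = sjkit.junction_deviation_test(matrix, logmat, estimates, assignment)
print(calls[calls.is_called][["gene_id", "log2fc_junction", "log2fc_gene",
                              "delta", "fdr"]])
```

prints (run as `examples/01_junction_deviation_pipeline.py`):

```
chrom  start    end gene_id  log2fc_junction  log2fc_gene  delta   fdr
 chrS 618828 619622   G0030            1.905       -0.409  2.314 0.038
 chrS 305610 308609   G0014           -1.747        0.365 -2.112 0.040
 chrS 569707 570973   G0027           -2.276        0.225 -2.501 0.050
```

Each row is a junction whose fold change deviates from its gene's overall
change by |delta| ≥ 1 log2 unit at FDR < 0.05 — e.g. the first junction rises
~1.9× in log2 while its gene barely moves, a hallmark of an isoform shift;
all three calls here land in genes carrying a planted switch. The
glutaminase-style switch call (`examples/02_gls_isoform_switch.py`) prints

```
GAC share of diagnostic reads: control=0.401, knockdown=0.107
delta proportion = -0.294 (negative: splicing shifts GLS.GAC->GLS.KGA), permutation p = 0.100
```

i.e. the knockdown condition shifts diagnostic-junction usage from the
GAC-specific junction toward the KGA-specific junctions, the direction such a
regulator loss is expected to produce (p = 0.100 is the smallest value an
exact 3v3 permutation can attain). The other `examples/` scripts cover event
classification with PSI, interactome G-tests, and the cohort statistics.

A thin CLI mirrors the shell-driven stages:

```sh
sjkit simulate --out study --seed 1
sjkit deviation --design study/design.tsv --gtf study/annotation.gtf --out calls.tsv
sjkit switch    --design study/design.tsv --gtf study/annotation.gtf --out switches.tsv --seed 1
```

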
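# mirpipe

Small-RNA isomiR-window miRNA quantification, count-based differential
expression, miRNA target CDF-shift analysis, and biomarker statistics —
the computational core of a two-cell-line knockdown-vs-control
transcriptomics study (the kind used to chase oncogene-regulated miRNAs in
pancreatic cancer), re-implemented as a tested, fully synthetic-data-driven
pipeline. Everything runs from generated toy data: no accession downloads,
no external aligners.

## Who this is for

Computational biologists who want a transparent, desk-scale
re-implementation of the standard small-RNA / mRNA knockdown analysis
stack — each statistical step written out and unit-tested against
independent oracles — either to audit the method choices or to run the
same analysis on their own count tables and SAM/FASTQ files.

## What it computes

**5′-anchored window quantification** (`mirpipe.quant`). Reads are
3′-adapter-trimmed by exact prefix search, filtered to 18–28 nt, and
mapped with zero mismatches to both genome strands. For each mature miRNA
the distinct sequences whose mapped 5′ end lies within ±3 nt of the
annotated 5′ end form its window; the max-count member is the *reference
sequence*, and abundance is

&nbsp;&nbsp;&nbsp;&nbsp;A = Σ counts of window sequences sharing the reference's 5′ position.

**Differential expression** (`mirpipe.diffexpr`). TMM normalization
(doubly trimmed, precision-weighted mean of per-feature log2 proportion
ratios M against a 75th-percentile-matched reference), a pooled
method-of-moments common NB dispersion φ, and the two-group
negative-binomial exact test: conditional on the equalized group sums
S₁ + S₂ = t, the two-sided p-value sums all outcomes no more likely than
the observed one, with Benjamini–Hochberg FDR and calls at FDR < 0.05.
At φ = 0 the test reduces exactly to the conditional binomial test.

**Target CDF shift** (`mirpipe.shift`). For a miRNA repressed after
knockdown, its target genes' log2 fold changes (LFCs) should shift
positive relative to all other expressed genes (repression release). The
shift is the two-sample Kolmogorov–Smirnov statistic
D = sup |F_targets − F_background| with the asymptotic Kolmogorov p-value
at √(mn/(m+n))·D, plus a signed median shift and a direction-consistency
flag against the miRNA's own LFC. Cross-cell-line statistics: one-sided
hypergeometric DE-set overlap, Pearson LFC concordance, and Fisher-exact
set enrichment with BH FDR.

**Biomarker and bench statistics** (`mirpipe.clinstats`). ROC/AUC
(Mann–Whitney with tie half-credit) with a DeLong 95% CI; median-split
Kaplan–Meier with the log-rank test and an O/E hazard ratio; 2^−ΔΔCt
relative qPCR quantification; ChIP percent-of-input; caliper tumor volume
V = length × width²/2.

**Synthetic data** (`mirpipe.synthetic`). Generators for every input:
random genomes with uniquely-mapping planted miRNA loci, isomiR read
populations (80% of 5′ ends at the annotated position, the rest spread
over ±1..3 nt; template-extended 3′ ends; per-base errors), NB count
matrices with planted fold changes and repression-release target sets, and
binormal/exponential clinical cohorts. Each generator returns a ground
truth sufficient to predict every downstream result.

## Worked example

The bundled demo study (two cell lines × 2 knockdown / 2 control small-RNA
samples over 24 miRNAs, 2500-gene count matrices, two miRNAs with planted
target release) runs in a few seconds:

```bash
python analysis/01_simulate_data.py
python analysis/02_quantify_smallrna.py
python analysis/03_differential_expression.py
python analysis/04_target_shift_concordance.py
python analysis/05_biomarker_stats.py
```

or, equivalently, `mirpipe run --seed 1 --out results/run`. With seed 1
the drivers print:

```
gene_line1: 78 DE features (39 up, 39 down), dispersion 0.076
mirna_line1: 8 DE features (3 up, 5 down), dispersion 0.000
mirna_line2: 9 DE features (4 up, 5 down), dispersion 0.000
shared DE miRNAs: ['mir-11', 'mir-12', 'mir-14', 'mir-19', 'mir-22', 'mir-8']
direction-consistent shift hits in both lines: ['mir-22', 'mir-8']
planted shift miRNAs: ['mir-22', 'mir-8']
overlap p = 1.27e-02, Pearson r = 0.995 (p = 4.40e-05)
AUC = 0.877 (95% CI 0.842-0.912); log-rank chi2 = 17.14 (p = 3.46e-05), HR = 1.57
```

Reading this: 8 and 9 miRNAs are called differentially expressed in the
two lines, sharing 6 — more than chance in a 24-miRNA universe
(hypergeometric p = 0.013) and with near-perfect fold-change concordance
(r = 0.995). Of the shared set, exactly the two miRNAs whose target genes
were simulated with a +0.5 log2 repression-release shift — `mir-22` and
`mir-8`, both repressed after knockdown — come out as direction-consistent
CDF-shift hits (KS p ≪ 1e-6); the four decoys do not. The clinical cohort,
generated under a binormal model targeting AUC 0.878, yields an observed
AUC of 0.877 and significantly worse survival above the median biomarker
level.

A `mirpipe` CLI exposes each stage on external files
(`quant`, `de`, `shift`, `overlap`, `enrich`, `roc`, `surv`, `ddct`,
`chip`, `run`, `validate`); `mirpipe quant --sam` ingests externally
mapped reads, discarding any alignment with mismatches or indels.

## Layout

- `src/mirpipe/` — the library: `synthetic`, `quant`, `diffexpr`,
  `shift`, `clinstats`, `pipeline`, `io`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite with brute-force/exact oracles
  (`tests/oracles.py`) and cross-checks against edgeR, lifelines and
  scikit-learn
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions, limitations
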
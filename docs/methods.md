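# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data do and do not establish about behaviour on real libraries.

## Small-RNA processing and 5′-window quantification

**Adapter trimming.** The insert ends at the leftmost exact occurrence of
the adapter's first 8 nt. If that prefix is absent (adapter truncated by
the read length), progressively shorter prefixes down to 5 nt are tried
anchored at the read's 3′ terminus; reads with no identifiable adapter are
rejected and counted. The 8-nt primary / 5-nt fallback thresholds trade
false adapter hits (a random 8-mer match occurs once per ~65 kb of insert)
against sensitivity to truncated adapters; they are fixed conventions, not
fitted values.

**Mapping.** Inserts of 18–28 nt (inclusive bounds) are located by exact
substring search on both genome strands; every zero-mismatch occurrence is
reported, and sequences without a perfect match are dropped. For
externally mapped data the SAM reader enforces the same contract: records
with indels, soft-clips, NM > 0, or a mismatch-bearing MD tag are
discarded, and per-sequence counts are taken over distinct read names so a
multi-mapped read is not double-counted.

**Window quantification.** Offsets are in mature-RNA orientation
(`offset = read_5p − locus_5p`, sign flipped on the minus strand), so
"upstream" is always toward the 5′ flank of the mature RNA. A distinct
sequence joins a locus's window when any of its alignments sits on the
locus's chromosome and strand within ±3 nt of the annotated 5′ end. Fixed
conventions where several answers are defensible:

- *Reference ties* break by smaller |offset| to the annotated end, then
  longer sequence, then lexicographic order — chosen purely for
  deterministic output.
- *Multi-mapping sequences* contribute their full count to every miRNA
  whose window captures one of their alignments (no fractional
  apportionment); paralog double-counting is visible in the window-detail
  output.
- A sequence with several in-window alignments counts once per miRNA; its
  representative placement is the alignment closest to the annotated end
  (upstream on ties).
- Abundance keys on the *reference's observed* 5′ position, which may
  differ from the annotated one; an empty window yields abundance 0 and a
  null reference.

## Differential expression

**TMM.** The reference sample is the one whose 75th-percentile
count-per-million is closest to the mean of those percentiles. Per-feature
log2 proportion ratios (M) and mean log2 abundances (A) against the
reference are computed over features nonzero in both samples, the most
extreme 30% by M (15% per tail) and 5% by A (2.5% per tail) are trimmed,
and the factor is 2 to the precision-weighted mean of the surviving M
values, rescaled so factors have geometric mean 1. Precision weights are
binomial delta-method variances evaluated on the *proportion* scale
(depth-free); this keeps factors exactly invariant to uniform rescaling of
any single library, at the cost of ignoring depth differences in the
weighting. With matched trim fractions the factors agree with edgeR's
`calcNormFactors` to about 1% on simulated data (asserted at 2.5% in the
suite; residual differences come from rank- vs quantile-based trimming and
the weight convention).

**Common dispersion.** Counts are placed on the common (geometric-mean)
effective library size; per feature and replicated group the moment
estimate (s² − m)/m² is formed, averaged across groups, clamped at zero,
and the median over features with within-group mean > 5 is returned. This
estimator is transparent but biased low at small replicate numbers: with
3 + 3 samples the median of a 4-df variance estimate sits near 0.84 of its
expectation, so φ = 0.2 is recovered around 0.16. Downstream tests that
state a dispersion therefore pass it explicitly; when the estimate is used
instead, calls at the FDR boundary are mildly anti-conservative (empirical
FDR ≈ 0.08 at a nominal 0.05 in the planted simulation). Conditional
maximum likelihood would reduce the bias and is deliberately out of scope.

**Exact test.** Counts are scaled to the common effective library size and
rounded half-up to pseudo-counts. Conditional on a feature's total t, the
first group's sum is tested against the null induced by modelling each
group sum as NB with mean proportional to its replicate number and
dispersion φ/replicates; the two-sided p-value sums the probabilities of
all outcomes with conditional mass ≤ the observed mass, using a relative
tie tolerance of 1e-7 (the same convention as `scipy.stats.binomtest`, to
which the φ = 0 case reduces within 1e-13). t = 0 gives p = 1 and LFC = 0.
LFC uses a 0.5 prior count per group mean so zero counts stay finite.
Group labels are ordered lexicographically, so LFC is
second-group-vs-first ("knockdown" vs "control" in the demo).

Because the test is discrete, its null p-values are *sub*-uniform
(conservative): P(p ≤ q) ≤ q with a deficit that shrinks as counts grow
(about 0.01–0.03 at the demo's count depths). The suite asserts two-sided
calibration bounds at a grid of quantiles rather than strict KS uniformity,
which no discrete exact test can meet at 10,000 features.

**FDR and calls.** BH step-up (via statsmodels); calls require FDR
strictly below the threshold, with direction from the LFC sign.

## Target CDF-shift analysis

The expressed-gene LFC table is strictly partitioned into the cognate
miRNA's expressed targets and everything else (the background). D is the
supremum absolute ECDF difference with the standard step construction (no
jitter on ties); p is the asymptotic Kolmogorov survival function at
√(mn/(m+n))·D, appropriate at the thousands-scale sample sizes this
analysis runs at — no exact small-sample permutation is attempted, and
results from fewer than 10 expressed targets are flagged underpowered but
still reported. The signed shift is median(targets) − median(background);
direction consistency requires its sign to oppose the miRNA's own LFC
(knockdown-vs-control orientation: a repressed miRNA releases its targets
upward).

The hypergeometric overlap tail is summed in log space (gammaln +
logsumexp) and equals exact rational enumeration on every universe ≤ 60
tested; the DE-set universe is the miRNAs detected above a configurable
mean count (default 10) in both cell lines, since the appropriate universe
is a property of the experiment, not of the method. Pearson concordance
uses the sample correlation with the t-distribution p-value (n − 2 df);
zero variance in either coordinate is reported as undefined.

## Clinical and bench statistics

AUC is the Mann–Whitney statistic with half-credit for ties (equal to the
trapezoidal area under the empirical ROC); the 95% CI uses the DeLong
placement-value variance, clipped to [0, 1] — chosen over the bootstrap
for determinism. The survival split assigns ties at the median expression
to the low group (a fixed convention); the log-rank statistic uses the
hypergeometric variance with at-risk sets including events at t, and the
hazard ratio is (O_high/E_high)/(O_low/E_low), consistent with the
log-rank test but biased toward the null relative to a Cox fit under
heavy censoring (the planted HR = 2 cohort recovers ≈ 1.6–2.1). A cohort
with no events at all yields p = 1 and an undefined HR. 2^−ΔΔCt uses
replicate-mean Ct values with the four SEMs propagated in quadrature and
mapped to the fold scale by the delta method; percent-input adjusts the
input Ct down by log2(1/fraction) before 100·2^(ΔCt); tumor volume is the
caliper formula length × width²/2 with a warning when width > length.

## Synthetic-data generators

The generators emulate the statistical structure of a two-cell-line
knockdown study so that every downstream stage has a computable truth:

- **Genome/loci**: uniform-random A/C/G/T chromosomes; mature loci of
  20–22 nt planted with ≥30 nt gaps and rejected unless their sequence
  occurs exactly once genome-wide across both strands, so perfect-match
  mapping is unambiguous and ±3 windows never overlap.
- **isomiR reads**: per sample and miRNA a Poisson count around the
  expected value; 5′ offsets drawn from P(0) = 0.80, P(±1) = 0.08,
  P(±2) = 0.015, P(±3) = 0.005 — mass concentrated at the annotated end, as
  in real libraries, while exercising every window slot — and 3′ ends
  varied uniformly over ±2 nt by template extension, which specifically
  exercises the rule that abundance keys on 5′ ends only. The adapter is
  appended and per-base substitution errors applied across the whole
  read; the truth table counts error-free reads per (miRNA, sample,
  offset). Real isomiR composition, ligation bias, non-templated
  additions, and hairpin structure are *not* modelled; passing tests show
  the bookkeeping is exact, not that the defaults match any particular
  library.
- **Count matrices**: NB with library-size-scaled means, common
  dispersion 0.1, 3 + 3 replicates, 10% of genes truly changed at
  |LFC| = 1 (a typical bulk knockdown regime); genes in a planted miRNA's
  target set get an additional 2^δ on the knockdown-group mean
  (δ = +0.5 by default). Dispersion 0 degenerates to Poisson.
- **Clinical cohorts**: binormal scores (cases N(√2·Φ⁻¹(AUC), 1),
  controls N(0, 1)) and exponential survival with the hazard multiplied by
  the target HR above the median expression, censored at 60 months with a
  baseline hazard of 0.03/month (≈ 2/3 events by follow-up end).

One global seed cascades to fixed per-component seeds, making every stage
bit-reproducible and independently re-runnable.

## Demo study sizing

The bundled configuration — 2 chromosomes × 20 kb, 24 miRNAs at ~300
expected reads each, 2 + 2 small-RNA samples per line, 2500 genes at 3 + 3
replicates, 150-gene target sets, a 349-sample cohort targeting AUC 0.878
and HR 2 — was sized so the whole pipeline completes in seconds on one
CPU while every planted effect is comfortably detectable: the miRNA fold
changes (|LFC| ≥ 1.1 at depth ~300) and the target shifts (δ = 0.5 against
LFC noise of ~0.4 SD over 150 targets) sit far from their detection
thresholds, so recovery is a correctness check rather than a power
experiment.

## Known limitations

- No mismatch-tolerant alignment or isomiR nomenclature; the internal
  matcher is exact-substring only and intended for toy genomes (SAM
  ingestion covers externally mapped data).
- The MoM dispersion estimator's small-sample bias (above) propagates to
  boundary FDR calls when the estimate, rather than a known φ, is used.
- The exact test covers two-group designs only; no GLM, tagwise or
  trended dispersion, or multi-factor designs.
- The KS p-value is asymptotic; below ~20 observations per sample it is
  only approximate (such results are flagged underpowered).
- The O/E hazard ratio is not a Cox estimate; no covariate adjustment.
- Target maps are inputs; no seed-match prediction or annotation-database
  retrieval is performed.
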
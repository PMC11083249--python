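# Methods

## Setting

Two inbred-line parents (P1, P2) and their F1 cross are profiled by bulk
RNA-seq in one or more tissues, with a handful of biological replicates
per group (the motivating design: 6 birds per group per tissue, 18
samples per tissue).  For each gene the mid-parent value

    MPV_g = (mean_P1(g) + mean_P2(g)) / 2

is the expression the F1 would show under purely additive inheritance.
The analysis asks, gene by gene, whether the F1 departs from the MPV and,
if so, where it sits relative to the two parents.

## Candidate filter

A gene enters the analysis when its raw count is greater than zero in at
least `ceil(n/2)` of the tissue's samples (9 of 18 in the motivating
design).  "Expressed" deliberately means the weakest possible reading,
count > 0, and the filter operates on raw counts so it is independent of
normalization.

## Normalization

Counts are scaled to counts per million (CPM) by total column count.
Library sizes are computed over **all** genes of the matrix, not only the
candidates, before the candidate subset is taken.

CPM measures *relative* expression.  If the F1 transcriptome's total
output genuinely differs from the parental mid-point — which happens
exactly when many genes are strongly over- or under-dominant — every F1
CPM value absorbs a common multiplicative offset, and even perfectly
additive genes appear shifted away from their MPV.  The pipeline
therefore applies an **F1 median-additivity alignment** by default: it
computes, per gene, d_g = log2((mean_F1 + 1)/(MPV + 1)), and rescales the
F1 columns by 2^(−median_g d_g).  This assumes the *median* candidate
gene expresses additively — the transcriptome-level analogue of the
"most genes are not differentially expressed" assumption behind TMM/RLE
scaling, and consistent with the empirical finding that additivity is the
predominant expression pattern in such crosses (roughly 80–95% of genes).
The alignment is a no-op (median ≈ 0) whenever the F1's composition is
already balanced, and can be disabled (`align=False` / `--no-align`).
The two parental groups are not mutually aligned: with the high parent
varying from gene to gene, their compositions are balanced by symmetry,
and CPM suffices.

TMM / median-of-ratios normalization is intentionally not implemented;
users with real data normalized elsewhere can construct a
`NormalizedMatrix` directly.

## Scales: linear means, log-scale tests

Group means, the MPV, and the high/low-parent assignment are always
reported on the **linear CPM scale**, so `mpv = (mean_p1 + mean_p2)/2`
holds exactly and the MPV is literally "the mean of normalized counts".

The t-tests, however, run by default on **log2(CPM + 1)** values, with
the MPV carried over as log2(MPV + 1).  Two wrong alternatives motivate
this hybrid:

- testing on the raw linear scale leaves the t-statistic's noise
  proportional to the (large) F1 variance at high expression, which
  costs most of the power for enhancing-dominance genes;
- defining the MPV as the *mid-point of the log means* (i.e. the
  geometric-mean parent) systematically mislabels genuinely additive
  genes, because the arithmetic mid-parent lies above the geometric one
  (Jensen's inequality; ~0.7 log2 units for an 8-fold parental
  difference).

Testing log-transformed observations against the log of the linear-scale
MPV keeps the additive null centered (the Jensen bias of the *sampling
noise* is only CV²/(2·ln2) ≈ 0.04 log2 units at dispersion 0.05, far
below the test's resolution) while stabilizing variances.
`scale="linear"` switches to untransformed tests; on that path the
pipeline is exactly invariant to rescaling all normalized values.

## The three tests and their correction

Per candidate gene:

1. **F1 vs MPV** — one-sample two-sided t-test of the F1 values against
   the (scalar) MPV.  A two-sample variant (`mpv_test="two-sample"`:
   Welch of the F1 values against the 12 pooled parental values
   re-centered onto the MPV) is available for sensitivity analysis.
2. **F1 vs high parent** — two-sample Welch-style test against the
   higher-expressing parent's samples.
3. **F1 vs low parent** — likewise against the lower-expressing parent.

Each of the three families is corrected separately across all candidate
genes with the **Benjamini–Yekutieli** step-up procedure (BH with the
harmonic-sum factor c(m) = Σ 1/i, valid under arbitrary dependence), and
a single alpha (default 0.05, strict inequalities) is shared by all
three.  BY is conservative; the null false-non-additive rate is well
below alpha in calibration runs.

### Variance moderation

With 6 replicates a per-gene variance estimate has 5 degrees of freedom,
and the plain t-test cannot separate an enhancing-dominance gene from the
MPV at realistic effect sizes once BY correction is applied.  The
pipeline therefore moderates variances by default with the standard
empirical-Bayes hierarchical model: per-gene variances get a scaled
inverse-chi-square prior whose parameters (prior df d0, prior value s0²)
are estimated from the observed variance distribution by the trigamma
method of moments; posterior variances

    s²_post = (d0·s0² + df·s²) / (d0 + df)

replace the raw ones and the t-statistics gain d0 degrees of freedom
(for the two-sample tests, a Welch–Satterthwaite combination of the
moderated variances).  Homogeneous variances (as on log scale with a
common dispersion) give d0 → ∞, i.e. complete pooling; heterogeneous
variances give small d0 and the procedure degrades gracefully toward the
ordinary t-test.  The implementation is cross-checked against
Bioconductor limma's `squeezeVar` in the test suite.  `moderate=False`
(`--no-moderation`) restores plain per-gene t-tests.

### Classification

The decision tree, evaluated in order, makes the categories mutually
exclusive (q denotes BY-adjusted p-values):

1. q_mpv ≥ alpha → `additive`
2. parental means exactly tied → `unclassified_nonadditive`
3. q_high < alpha and mean_F1 > mean_high → `over_dominance`
4. q_low < alpha and mean_F1 < mean_low → `under_dominance`
5. q_high ≥ alpha and q_low < alpha → `enhancing_dominance`
6. q_low ≥ alpha and q_high < alpha → `suppressing_dominance`
7. otherwise → `unclassified_nonadditive`

Over/under-dominance precede the dominance checks because they are the
stronger, more specific calls (an over-dominant gene usually also
differs from the low parent).  Enumerating all significance/direction
combinations shows the four named non-additive classes are not
exhaustive — e.g. a gene significantly different from the MPV *and* from
both parents while lying strictly between them fits none of them —
hence the explicit `unclassified_nonadditive` category; published
per-class counts in this literature likewise do not sum to the
non-additive totals.  `not_testable` is reserved for genes whose tests
return no finite q-value; with the degenerate-input conventions below it
is normally empty.

### Degenerate inputs

Zero-variance situations are resolved by convention rather than NaN, so
downstream set algebra stays total: constant values with zero mean
difference give (t=0, p=1); constant values with a non-zero difference
give (±inf, 0).  Exact parental ties yield high_parent = "tie" and block
the dominance categories.

## Differential expression

`call_degs` implements the conventional significance contract — BH-FDR
< 0.05 **and** |log2FC| > 1, both strict — with Welch's unequal-variance
t-test on log2(CPM + 1) and log2FC defined as the difference of group
means on the log scale.  This is deliberately *not* a negative-binomial
GLM (no dispersion estimation, no exact test); the package's validation
surface is truth recovery on simulated data and the threshold contract,
not equivalence with any particular DEG engine.  By default the caller
tests all genes of the supplied matrix; pass the candidate-filtered gene
list to restrict it (the CLI applies the filter unless `--all-genes`).

## Reporting

- Category counts always partition the candidates; additive/non-additive
  fractions are computed over testable genes and rendered as percentages
  with one decimal, rounding half away from zero.
- Top-N genes rank by summed normalized expression over a chosen sample
  set, ties broken lexicographically by gene id.
- PCA (QC only) runs on gene-centered log2 values; each component's sign
  is fixed by making its largest-magnitude loading positive, so
  coordinates are bit-for-bit reproducible.

## The simulator

`simulate_cross` draws, per gene and sample, NB(mean, dispersion) counts
with variance = mean + dispersion·mean², where the mean is the gene's
mode-determined expectation times a per-sample library factor
(log-normal, mean exactly 1, CV = `libsize_cv`).  Mode expectations use
a low-parent mean `base_mean` (default 100 counts, a moderately
expressed gene) and a high-parent mean `base_mean·2^effect_log2`:

| mode | mu_F1 |
|---|---|
| additive | (mu_P1 + mu_P2)/2 |
| enhancing_dominance | max(mu_P1, mu_P2) |
| suppressing_dominance | min(mu_P1, mu_P2) |
| over_dominance | max · 2^overshoot_log2 |
| under_dominance | min / 2^overshoot_log2 |
| null_equal | mu_P1 = mu_P2 = mu_F1 = base_mean |

Defaults: n_per_group = 6 (the motivating design), effect_log2 = 2,
overshoot_log2 = 1, dispersion = 0.1, libsize_cv = 0.1.  The
higher-expressing parent alternates between P1 and P2 gene-by-gene, so
"high parent" is never confounded with a line; `null_equal` genes
measure the false-non-additive rate.  Identical configs (including the
seed) give byte-identical output.

**What the simulator does not emulate** — and what passing tests
therefore do not establish about real data: gene-level expression
heterogeneity (all low parents share one `base_mean`), gene-specific
dispersions (moderation meets its most favorable, fully-poolable case),
sex or batch effects, between-gene correlation, multi-modal effect
sizes, and annotation artifacts (multi-mapping, overlapping genes).  On
real data the moderation prior will be wider and recovery rates
correspondingly lower than the simulation figures.

## Problem sizes used in validation

The recovery benchmark classifies 1,200 genes (200 per mode; effect_log2
= 3, overshoot_log2 = 1.5, dispersion = 0.05, n = 6) and requires ≥90%
per-class recovery; calibration uses 5,000 null genes.  Multiple-testing
routines are checked against a literal step-up oracle on 1,000 random
p-vectors (length ≤ 200) to 1e-12.  All are fast enough to run in the
default test suite.
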
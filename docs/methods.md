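# Methods

This note documents the statistical model, the synthetic study conditions,
the numerical choices, and what the test suite does and does not
demonstrate about real data.

## The weighted proportions test

The differential-expression test compares, per gene, the proportion of a
sample's mapped reads assigned to that gene between two replicated groups
(induced versus control).  Proportions use the *library size* (all mapped
reads) as denominator, not the column sum of the analysed gene set, so
subsetting genes does not change any test result.

Model: for replicate i with x_i counts out of n_i mapped reads, the
proportion p_i = x_i/n_i has mean p and variance p(1−p)(1/n_i + θ).  The
extra-variance parameter θ captures between-replicate (biological +
technical) dispersion on the proportion scale; θ = 0 recovers pure
binomial sampling.  Per group:

* pooled proportion p̃ = Σx_i / Σn_i;
* method-of-moments θ̂ = s²/(p̃(1−p̃)) − mean(1/n_i), clamped at 0, where
  s² is the sample variance of the p_i;
* inverse-variance weights w_i ∝ 1/(1/n_i + θ̂), normalised to 1;
* p̂ = Σw_i p_i and v̂ = p̃(1−p̃)/Σ[1/(1/n_i + θ̂)].

The statistic (p̂_A − p̂_B)/√(v̂_A + v̂_B) is referred two-sidedly to a t
distribution with Welch–Satterthwaite degrees of freedom computed from
(v̂_A, v̂_B) and the replicate counts.  Genes with zero counts in both
groups are untestable (stat 0, p 1) and are excluded from the BH family so
they cannot dilute the FDR.  q-values are Benjamini–Hochberg step-up
(via `statsmodels.stats.multitest.multipletests`).

**Calibration.**  With 4 vs 4 replicates the construction is slightly
conservative — this is shared with the ordinary Welch t-test, whose
p-value distribution at m = 4 deviates from uniform by a Kolmogorov–
Smirnov distance of roughly 0.01–0.02 even on exactly normal data,
because the 3-degree-of-freedom variance estimate makes the t reference
approximate.  At a well-measured operating point (group proportion 0.1,
θ = 0.005, beta shape ≈ 20) the empirical type-I error at α = 0.05 is
≈ 0.04 and the KS distance ≈ 0.015.  At transcriptome-realistic tiny
proportions with large θ/p ratios the per-replicate proportion
distribution is strongly skewed and the test becomes markedly
conservative — a property of this test family, to keep in mind for
low-abundance genes.  The calibration harness
(`simulate_null_groups`) therefore evaluates the test in the regime where
its normal-approximation assumptions hold; it is a marginal statistical
null, not a coherent transcriptome.

**Fold changes.**  log2 FC = log2((m_T + c)/(m_C + c)) on per-cell mean
RPKM, with pseudocount c = min(5th percentile of the nonzero cell means,
RPKM equivalent of a single read at the median gene length and mean
library).  On real transcriptome-shaped data with a long low-expression
tail the percentile term governs and c is negligible for expressed genes;
the one-read floor prevents the percentile from dominating typical genes
on dense data (count matrices without a low tail), while still keeping
fold changes finite at zero means.  c is configurable.

Strict DEG filter: q < 0.05 and |log2 FC| ≥ 1 (2-fold, applied
two-sidedly).  Relaxed filter: q < 0.05 and |log2 FC| ≥ 0.2.  All four
thresholds (0.05, 2, 0.2, and the CRF threshold 0.1 below) are named
configuration keys.

## Off-target correction

The empty-vector control line carries the ethanol-induction machinery but
no TPS, so its ethanol response estimates off-target effects.  Two modes:

* **Residualization** (array-style): OLS of the per-gene iTPS
  ethanol-minus-water difference on the alcR difference, by default
  without intercept (differences are centred contrasts; intercept by
  flag).  "Weighting by the coefficient" is implemented as subtraction of
  the fitted component, the only reading that leaves the corrected signal
  orthogonal to the off-target predictor; correction is therefore
  idempotent to numerical precision.  For the no-intercept fit the
  reported R² is the uncentred statsmodels definition.
* **Flagging** (RNA-seq style): genes passing the strict filter in both
  the iTPS and alcR contrasts are reported, split by direction;
  same-direction genes are excluded from all downstream analyses.
  Flagging never alters any statistic — it only removes genes.

One model is fitted per contrast pair (per line/timepoint), not pooled.

## CRF and group assignment

CRF = unweighted arithmetic mean of a gene's log2 fold changes over the
observed panel contrasts (missing cells skipped, never zero-filled; the
panel serialises missingness as `NA` precisely to keep "not measured"
distinct from "no change").  Genes with fewer than `min_obs` (default 3
of 9) observed contrasts get no CRF: a mean over 1–2 array contrasts is
noise-dominated.

Assignment, for genes passing the chosen responsiveness filter (default
relaxed, matching the filter used for category inspection; strict by
flag): |CRF| > 0.1 with matching sign → G1, opposing sign → G2, otherwise
G0.  The 0.1 threshold is applied two-sidedly and with strict inequality
(CRF exactly ±0.1 → G0).  Genes failing the filter are unassigned; the
output is a partition, invariant under joint sign-negation of the
response and the panel.  Responsive genes absent from the panel default
to G0 (flagged `in_panel = False`; configurable to unassigned), mirroring
an analysis restricted to the gene universe shared with the array panel.

The context-dependence diagnostic flags genes whose panel row contains
both a value ≥ +thr and a value ≤ −thr (inclusive): such genes respond to
sugar in opposing directions across contexts, one documented reason a
truly sugar-responsive gene can end up in G0.

## BIN enrichment display

Fold changes failing the chosen filter are set to exactly zero (never
dropped), then averaged per functional category — zeros included — so a
populated category where nothing passes shows 0, while a category with no
member genes under the current subset shows NA.  Categories form a prefix
tree; ancestor averages cover the union of descendants' and directly
assigned genes (cumulative display; direct-only by flag).  A gene mapped
to several categories contributes to each but counts once within one.

## Cross-dataset comparison

External response vectors join on the upper-cased gene-id intersection.
Sign concordance counts same-sign, opposite-sign and zero-containing
pairs; zeros ("did not respond") are never tie-broken into a direction.
The regression is OLS of the iTPS response on the external vector with R²
the squared Pearson correlation.  Per-group comparison restricts to genes
passing the filter in each of {all, G1, G2, G0}; the filter inequality is
FDR < 0.05 (one published figure legend prints "FDR > 0.05", which this
implementation treats as a typo for "<").

## Synthetic study conditions

Defaults (all configurable): 2,000 genes; classes direct 20%,
indirect 15%, orthogonal 15%, off-target 1%, null 49% — i.e. 40/30/30
direct/indirect/orthogonal among the sugar-informative responsive genes —
apportioned deterministically by floor-then-largest-remainder; effect
magnitudes |log2 FC| ~ U(1, 2) with random sign (comfortably above the
strict threshold, so recovery is power-limited rather than
threshold-ambiguous); |CRF| ≈ 0.5 for sugar-responsive classes versus
≤ 0.05 for orthogonal genes; 9 panel contrasts with per-contrast noise
sd 0.15 log2 (array-scale error; CRF standard error ≈ 0.05 over ~8
observed contrasts) and 10% missing cells; 10% of sugar-responsive genes
get context-dependent rows (a zero-sum ±1.5 pattern that preserves the
row mean, hence the CRF); gene ids are synthetic AGI-like strings.

Counts: factorial design iTPS/alcR × ethanol/water × timepoints × 4
replicates; baseline abundances log-normal with 2.0 log2 sd (~100-fold
range); libraries 20 M reads ± 20% (matching the >20 M reads/sample of
the motivating experimental design); the simulated genes take 10% of the
library at baseline, and proportions keep the *baseline* total as
denominator — library sizes count all mapped reads, of which the analysed
genes are a subset, so cross-gene competition from the planted shifts is
buffered by the unmodelled majority of the transcriptome.  (Renormalising
within the gene set instead would shift every null gene by the net
abundance multiplier, ~0.3 log2 here — a composition artifact this choice
deliberately avoids.)  Replicate proportions are beta-binomial with
θ = 2.5e-7 by default: θ is an absolute extra-variance on the proportion
scale, and at the median simulated proportion (5e-5) this gives a
between-replicate CV of ≈ 7%, consistent with an experiment in which
>55% of detected transcripts clear FDR < 0.05 with quadruplicates of
pooled rosettes grown in one chamber.  A log-normal noise mode with
matched CV is available to probe robustness under misspecification.

The off-target class is planted with stronger shifts (|log2 FC| ~
U(2, 3), same sign in both genotypes) and in the upper half of the
abundance distribution: it models the handful of *observed* empty-vector
artifacts, which are by construction detectable in both lines, so the
flagging recovery measures the flagging logic rather than detection power
at the depth floor.

External signature modes: `reciprocal` (opposite to the planted response
for direct genes, concordant for indirect genes — the SnRK1-like
structure), `concordant`, and `mixed` (75/25 opposite/same among
responsive genes by default), each plus Gaussian noise (default sd 0.1).

**What passing tests show — and don't.**  The generator matches the DE
test's variance model (beta-binomial), plants effects well above
thresholds, and draws classes independently of abundance (except the
off-target class).  Recovery rates near 100% therefore demonstrate
correctness of the pipeline's logic under its own assumptions, not
expected performance on real tissue: real data add unmodelled structure —
correlated genes, abundance-dependent dispersion, batch effects,
cross-hybridising families, and panel contrasts that are themselves
correlated experiments rather than independent noisy replicates of one
CRF.

## Numerical choices and degenerate inputs

* Tables are TSV (UTF-8, Unix newlines), floats at 9 significant digits,
  `NA` for missing; write-then-read reproduces values to ≥ 6 significant
  digits.  Gene ids compare case-insensitively (upper-cased on load).
* BH q-values are monotone-enforced and order-preserving; q ≥ p.
* A contrast cell with < 2 replicates, an unknown selector, a gene with
  zero length, a panel with zero contrasts, fractions not summing to 1,
  or θ < 0 raise typed errors before any computation.
* Zero estimated variance with identical groups yields (stat 0, p 1)
  rather than NaN.
* Pipeline runs are byte-reproducible for a fixed configuration: stage
  seeds derive from the single config seed via `numpy` seed sequences,
  and output headers carry the package version, a configuration hash and
  the seed.
* Problem sizes in the test suite (2,000-gene fixtures, 10,000-gene null
  calibration, 1,000 oracle vectors) are chosen so the whole suite runs
  in a few seconds while keeping Monte-Carlo error well inside the
  asserted bands.

## Known limitations

* The exact internals of the proprietary implementation of the weighted
  proportions test family are not public; the contract above (moments
  clamp, inverse-variance weights, Welch–Satterthwaite reference) is this
  package's pinned, oracle-checkable reading.
* The relaxed-filter linear threshold is exposed as `fc_relaxed = 1.1487`
  (2^0.2 ≈ 1.149).
* No negative-binomial GLM alternative, no batch covariates, no
  between-sample normalisation beyond per-million scaling.
* The BIN display is the filtered-average heatmap only; no
  Wilcoxon/Fisher category tests.
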
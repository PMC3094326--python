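# Methods

This note documents the models and procedures implemented in subtypeforge,
the parameters that matter and their defaults, the numerical choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Preprocessing

Raw linear intensities are scaled per sample so that the trimmed mean
(discarding 2% from each tail by default, the usual single-channel array
convention; configurable in `[0, 0.25)`) equals a common target of 500,
then log2-transformed. Quantile normalization then forces every sample
column onto the common per-rank mean distribution; ties within a column
receive the mean of the reference values over the tied ranks.

Numerical note: quantile normalization is exactly idempotent on tie-free
data. With ties, the mean-of-tied-ranks rule perturbs the reference
distribution by `(m − r)/n` per tied rank on a second application, so
idempotency holds only to that order; this is shared by the standard
reference implementations of the same rule.

Cohort eligibility applies QC flags first (RNA quantity, RNA quality,
array quality — all three must pass), then the follow-up rule: at least
3 years of follow-up, waived for patients who died of disease.

## Classifier probe selection

Every probe is screened against each of a curated list of pivotal genes
(anchor genes with known roles in breast-cancer biology; the list is an
input). A probe qualifies on correlation if, against at least one pivotal
gene other than itself, `|Pearson r| ≥ 0.5` or the degree-2 polynomial fit
has `R² ≥ 0.5`. Correlation thresholds are effect sizes, not p-values: at
cohort sizes in the hundreds, trivially small correlations are
"significant", so a size threshold is the meaningful screen. The quadratic
criterion is the R² of the least-squares parabola, which reduces to the
squared linear correlation when the curvature term vanishes — a linear
relationship therefore also passes the quadratic screen, by construction.

Qualifying probes are then filtered on mean log2 intensity (default
`log2(100)`), range (default 2 log2 units), and Pearson kurtosis
`m4/m2² ≤ 3` (population moments, no excess subtraction, no small-sample
correction). Low kurtosis selects flat or multi-modal densities — probes
that separate sample groups — and rejects spiky unimodal or heavy-tailed
probes. Constant probes have undefined correlation/kurtosis and never
qualify. All thresholds are configurable; the defaults above are declared
choices, not fitted values.

## Two-step k-means and centroid classification

Step 1: per-probe z-scoring, then Euclidean k-means over the samples
(lloyd, best of `n_restarts = 100` random initializations by
within-cluster sum of squares, seeded). Step 2: per-cluster centroids
(means of member columns on the z-scale) are computed, every sample is
reassigned to the centroid with the highest Spearman correlation, and
centroids are recomputed — iterated to a fixed point (at most 50 sweeps).
Spearman is the default reassignment metric because rank correlation
survives platform and scale distortions (single-sample-predictor
practice); Pearson is available by flag. Clusters emptied during
reassignment are dropped with a warning and K reduced.

Labels I…K are assigned deterministically: when an anchor probe (e.g. an
estrogen-receptor probe) is supplied, clusters are ordered by ascending
mean anchor expression (most ER-negative first) with size breaking ties;
otherwise by descending size, then lowest member index. The fit-time
per-probe center/scale is stored in the model and re-applied verbatim when
classifying new samples, so no information leaks from the classification
cohort into the standardization. Classification requires ≥ 50% of the
model's probes to be resolvable in the new profile; correlation ties are
broken toward the earlier label with a warning. Cross-platform projection
maps target probe ids through a probe→gene relation and averages all
matching external rows per target id.

## Bimodal marker cut-points

ER, PR and HER2 expression on the log2 scale is bimodal: a negative and a
positive mode. A two-component univariate Gaussian mixture with unequal
variances is fitted by EM (tolerance 1e-8, up to 2000 iterations, best of
20 random restarts, seeded). The cut-point is the point between the two
component means where the weighted component densities — hence the
posterior membership probabilities — are equal; it is found by root
bisection of the log-density difference, with a grid fallback when extreme
weights push the crossing outside the bracket. The posterior-equality cut
was chosen over the mixture-density minimum for stability under unequal
variances; the density-minimum cut is available by flag. Fits whose modes
are closer than half the pooled SD are flagged weakly bimodal. Calls are
strict: a value exactly at the cut-point is negative.

## Risk scores

The 21-gene recurrence score follows the published predictive model: group
scores GRB7g = max(8, 0.9·GRB7 + 0.1·HER2), ERg = (0.8·ER + 1.2·PGR +
BCL2 + SCUBE2)/4, PROLIFg = max(6.5, mean of BIRC5/KI67/MYBL2/CCNB1/AURKA),
INVg = mean(CTSL2, MMP11); unscaled RS = 0.47·GRB7g − 0.34·ERg +
1.04·PROLIFg + 0.10·INVg + 0.05·CD68 − 0.08·GSTM1 − 0.07·BAG1; scaled
RS = clamp(20·(RSu − 6.7), 0, 100); groups low < 18 ≤ intermediate < 31 ≤
high. Inputs are on the assay's 0–15 reference scale; the default mapping
from cohort log2 values is an affine rescale of the per-cohort range to
[0, 15] (`reference_normalize`), with fixed anchors available for external
cohorts. How real platform probe-sets are averaged into the 16 genes is a
user-supplied mapping, not hard-coded.

The template score is the Pearson correlation of a tumor profile with a
good-prognosis template over the shared genes (≥ 50% overlap required);
score < 0 is high risk, ≥ 0 low risk. Profiles and template are compared
as per-gene deviations from the cohort mean: correlating raw intensities
would let the baseline expression profile (shared by every sample) inflate
all correlations and mask the prognostic contrast.

## Exact r×c Fisher test

Two-sided p-values use the probability-mass criterion: the sum of
multivariate-hypergeometric probabilities of all same-margin tables whose
probability does not exceed the observed table's (ties included within a
relative tolerance of 1e-7). This criterion reproduces the conventional
two-sided values for the 2×2 and r×c tables it is checked against.

Three routes:

* **2×c, exact integers.** A 2×c table is determined by its first row, and
  each table's probability is `∏ C(c_j, x_j) / C(n, r_1)`, so the whole
  computation stays in big integers: a backward DP over columns (processed
  in decreasing-total order, which prunes best) records the min/max/sum of
  completion weights per state, and a forward pass expands only paths whose
  min–max interval straddles the observed weight, merging paths with equal
  partial products. Ties are exact.
* **r×c, log-space network DP.** The same pruned-network idea with the
  path length `Σ −log a_ij!`: rows are sorted descending and the largest
  row is implied (forced per column), backward layers store per-state
  min/max completion lengths (float32, with a 1e-3 nat safety slack on all
  pruning comparisons) and the completion mass in an exponentially tilted
  linear scale with per-layer offsets; the forward pass merges paths whose
  accumulated lengths agree to 1e-9 (drift bounded well under the 1e-7 tie
  tolerance). The total probability over all same-margin tables is
  re-accumulated on every run and must equal 1 to 1e-9, otherwise the
  function raises rather than return a silently wrong value.
* **Monte Carlo.** Patefield-style sampling of tables with fixed margins
  (`scipy.stats.random_table`), seeded, with `p̂ = (1 + hits)/(B + 1)`.

Degenerate margins (empty rows/columns, single row or column) give p = 1.
Tables whose state space exceeds a configurable budget raise an error
advising Monte-Carlo mode. One such table matters in practice: a 4×6
T-stage×subtype table with n = 327 has an ambiguous-path frontier in the
tens of millions (the classical Fortran network implementation also
overflows its workspace on this table), so its p-value is computed by
seeded Monte Carlo with B = 2×10⁷ (standard error ≈ 5% of the estimate,
far below the single printed significant figure it is compared at).

## Survival statistics

Kaplan–Meier estimation wraps the standard product-limit fit (censored
observations tied with events count as at risk for the event). The
k-sample log-rank test is implemented directly: per distinct event time,
observed and expected events per group and the hypergeometric covariance
with ties; the statistic is `z' V⁻¹ z` over k−1 groups against chi-square
with k−1 df. It is cross-checked in the tests against an independent
implementation and agrees to 1e-6. With zero events the test is degenerate
and returns p = 1 with a warning. Calibration: empirical type-I error at
nominal 0.05 over 2000 null simulations (equal exponential arms, 50/arm)
falls within [0.03, 0.07]; the residual anti-conservatism (~0.06) is the
chi-square approximation at this sample size, not an implementation
artifact.

Cross-dataset subtype concordance: both sides are reduced to per-gene,
per-subtype means, z-scored per gene, vectorized, and Pearson-correlated;
the null permutes the second dataset's subtype labels across samples B
times (label counts are preserved by permutation, so no subtype can
vanish); `p = (1 + #{r_perm ≥ r_obs})/(B + 1)`, which cannot undercut
1/(B+1).

## Synthetic cohort generator

The generator plants, with one mandatory seed: six expression subtypes at
group sizes (37, 34, 41, 81, 41, 93) (total 327, the study's cohort
shape); 23 pivotal genes whose per-subtype means sit on an evenly spaced
grid (±1.55 spread units, random order per pivot, jitter 0.12) scaled by
1.5 log2 units; a classifier block of 120 probes — 40 linear in pivotal
gene 1, 40 exactly quadratic in pivotal gene 2, 40 linear in random pivots
— at correlation targets r = 0.9 / R² = 0.9 with residual noise SD 0.35;
ER/PR/HER2 marker genes drawn from two-component mixtures whose
per-subtype positivity rates follow the study's cross-tabulation (e.g.
subtype I 0% ER+, subtype V 100% ER+/PR+/HER2−); 13 recurrence-score gene
rows with proliferation high in subtypes I/II and the ER axis high in
IV/V/VI; and 300 unstructured noise probes.

Design choices worth recording:

* *Grid-based pivot means.* Random Gaussian subtype means occasionally
  collapse to a near-unimodal layout, which makes downstream probes
  Gaussian-shaped (kurtosis ≈ 3) and flaky against the kurtosis filter.
  The evenly spaced grid keeps every pivot's pooled density flat or
  multimodal, which is the very premise of the kurtosis screen.
* *Mildly curved quadratic block.* The quadratic probes place the parabola
  vertex 7–9 SD below the pivot's range. A vertex inside the range folds a
  multimodal density into a heavy right tail — which the kurtosis filter
  correctly rejects — so strongly folded "quadratic" probes would never
  appear in a kurtosis-screened classifier in the first place. Pivotal
  gene 2's subtype layout is pinned with the heaviest subtypes at the
  extremes for the same reason.
* *Marker mixtures.* Per-gene components (log2): ESR1 neg N(6.5, 0.45²) /
  pos N(11.0, 0.5²); PGR neg N(6.5, 0.35²) / pos N(11.5, 1.45²); ERBB2
  neg N(7.0, 1.1²) / pos N(12.0, 0.4²). The minor mode is tight and the
  major mode wide because at skewed positivity rates (~81% PR+, ~23%
  HER2+) an equal-variance mixture drifts above kurtosis 3 (the two-point
  limit is 1/(w(1−w)) − 3); these parameters keep the pooled kurtosis in
  2.1–2.7 with the two modes still ≈ 5 SD apart, so status calls remain
  ~99% separable.
* *Survival.* Exponential times with per-subtype baseline metastasis
  hazards (0.030, 0.085, 0.035, 0.055, 0.008, 0.035 events/year — the
  observed metastasis gradient II > IV > VI ≈ III ≈ I > V), censoring
  uniform on [3, 15] years of follow-up. Regimen multipliers apply only in
  subtype IV (CMF ×3.0, CAF ×0.6, no-chemo ×1.5): the anthracycline-
  sensitive stratum. Subtype V's hazard ignores chemotherapy entirely: the
  endocrine-only stratum. Overall survival is metastasis time plus an
  independent exponential residual (hazard 0.7× baseline) — a convenience
  that guarantees OS ≥ MFS without modeling post-relapse survival.
* *Two seeds.* `structure_seed` (defaults to `seed`) fixes the
  population — centroids, anchors, effect sizes — while `seed` draws the
  samples, so two configs sharing a `structure_seed` are independent
  cohorts from the same population; this is what makes cross-cohort
  centroid classification a meaningful test.

What passing tests on this generator do and do not show: they demonstrate
that each stage recovers the structure it assumes (probe-selection
sensitivity ≥ 0.95 at false-positive rate ≤ 0.01, subtype ARI ≥ 0.9 within
and across cohorts, cut-point error < 0.3 log2 units, marker-call accuracy
≥ 97%, the subtype-IV-only chemotherapy contrast at power ≥ 0.8 with
60/arm) under clean Gaussian-mixture noise. They do not demonstrate
robustness to probe-level array noise models, batch effects, correlated
censoring, or cohort heterogeneity — none of which the generator emulates.

## Problem sizes used

The default test and acceptance runs use the 327-sample default cohort,
2000 null simulations for log-rank calibration, 50 simulated cohorts per
treatment-contrast power estimate, B = 2×10⁷ Monte-Carlo tables for the
one infeasible exact Fisher table, and the exhaustive oracle comparison
over all 2×3 and 3×3 tables with total ≤ 12 (≈ 3.1×10⁵ tables). These
sizes were chosen so the full suite completes in a few minutes on one CPU
while keeping every Monte-Carlo standard error at least an order of
magnitude below the tolerance it is checked against.

## Known limitations

* The exact r×c network DP is practical up to roughly the state-space
  budget (~10⁸ state×layer cells); beyond that it refuses rather than
  thrash, and the seeded Monte-Carlo mode is the supported route.
* Several published contingency rows in the source cross-tabulations
  (distant metastasis, TNM stage, local/regional relapse) are internally
  inconsistent with their own subtype totals; they are not reproduced here
  and no corrected counts are guessed.
* Quantile normalization operates on whatever matrix it is given; whether
  to normalize cohorts jointly or separately is the caller's decision.
* Marker cut-points default to being fitted on the matrix provided;
  restricting the fit to a reference cohort and applying the cut elsewhere
  is the caller's composition of `fit_bimodal_cutpoint` + `call_status`.
* The recurrence-score reference normalization (cohort range → 0–15) is a
  declared default, not a calibration against the commercial assay; no
  clinical equivalence is claimed.
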
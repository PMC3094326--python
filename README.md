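# subtypeforge

Molecular subtyping of breast cancer from microarray gene expression, as a
tested, reusable pipeline. Bulk expression profiling splits breast tumors
into subtypes with distinct biology and — crucially for treatment choice —
distinct responses to adjuvant chemotherapy regimens (CMF vs. anthracycline-
containing CAF) and to endocrine therapy alone. This package implements the
full analysis chain that supports such a study, for computational biologists
who want to run, audit, or stress-test each stage:

* **Preprocessing** — per-sample trimmed-mean scaling (target 500), log2
  transform, quantile normalization.
* **Classifier probe selection** — screen every probe-set by linear
  (Pearson r) and quadratic (degree-2 R²) correlation against a curated
  list of *pivotal genes*, then filter on mean intensity, dynamic range,
  and Pearson kurtosis m₄/m₂² ≤ 3 (low kurtosis marks the flat/bimodal
  densities that make robust classifiers).
* **Subtype discovery** — two-step k-means: Euclidean k-means on per-probe
  z-scores (best of many restarts) seeds the partition; samples are then
  iteratively reassigned to the centroid they Spearman-correlate with best,
  to a fixed point. New samples and external datasets are classified by
  nearest centroid, with probe→gene averaging across platforms.
* **Receptor status from expression** — ER/PR/HER2 are bimodal on the log2
  scale; a two-component Gaussian mixture is fitted by EM and the cut-point
  placed at posterior equality, `w₁·φ(x;μ₁,σ₁) = w₂·φ(x;μ₂,σ₂)`.
* **Recurrence-risk scores** — the 21-gene recurrence score
  `RSu = 0.47·GRB7g − 0.34·ERg + 1.04·PROLIFg + 0.10·INVg + 0.05·CD68 −
  0.08·GSTM1 − 0.07·BAG1`, scaled `RS = clamp(20·(RSu − 6.7), 0, 100)`
  with low/intermediate/high bands at 18 and 31; and a good-prognosis
  template-correlation score (negative correlation ⇒ high risk).
* **Statistics** — an exact Fisher–Freeman–Halton test for r×c contingency
  tables (probability-mass two-sided criterion, big-integer arithmetic for
  2×c, a pruned log-space network DP for r×c, and seeded Monte-Carlo for
  tables beyond exact reach), Kaplan–Meier estimation, the k-sample
  log-rank test, and a label-permutation test for cross-dataset concordance
  of subtype mean profiles.
* **Synthetic cohorts** — a generator that plants all of the above
  structure (six subtypes at the study's group sizes, bimodal markers at
  the study's positivity rates, subtype×regimen survival hazards) so the
  whole pipeline is testable offline with known ground truth.

## Worked example

```python
from subtypeforge import (SyntheticConfig, generate_cohort, two_step_kmeans,
                          fit_bimodal_cutpoint, call_status, fisher_exact_2xc,
                          logrank_test, truth_report)
from subtypeforge.feature_selection import (PivotalGeneSet, ProbeFilterCriteria,
                                            select_classifier_probes)
from subtypeforge.stats_survival import ContingencyTable
import numpy as np

expr, clinical, truth = generate_cohort(SyntheticConfig(seed=11))
print(f"cohort: {expr.shape[0]} probes x {expr.shape[1]} samples")

selected = select_classifier_probes(
    expr, PivotalGeneSet(truth["pivotal_probes"]), ProbeFilterCriteria())
print(f"selected classifier probes: {len(selected)}")

labels, model = two_step_kmeans(expr.subset_probes(selected),
                                k=6, n_restarts=50, seed=11)
print("subtype sizes:", {lab: labels.count(lab) for lab in model.labels})
print("ARI vs planted subtypes:", truth_report(truth, fitted_labels=labels)["ari"])

er = expr.probe_values("ESR1")
cut = fit_bimodal_cutpoint(er, seed=11, role="ER")
print(f"ER cut-point: {cut.cutpoint:.2f} log2 units "
      f"(planted {truth['cutpoints']['ESR1']:.2f})")

tab = ContingencyTable.from_labels(call_status(er, cut), labels)
print(f"ER x subtype Fisher p = {fisher_exact_2xc(tab):.3g}")

groups = [(clinical.loc[np.array(labels) == lab, "mfs_time_years"].to_numpy(),
           clinical.loc[np.array(labels) == lab, "mfs_event"].to_numpy())
          for lab in model.labels]
res = logrank_test(groups)
print(f"metastasis-free survival log-rank: "
      f"chi2 = {res.chi2:.1f}, df = {res.df}, p = {res.p:.3g}")
```

prints:

```
cohort: 459 probes x 327 samples
selected classifier probes: 151
subtype sizes: {'I': 93, 'II': 81, 'III': 41, 'IV': 41, 'V': 37, 'VI': 34}
ARI vs planted subtypes: 1.0
ER cut-point: 8.68 log2 units (planted 8.61)
ER x subtype Fisher p = 1.51e-53
metastasis-free survival log-rank: chi2 = 21.0, df = 5, p = 0.000824
```

Reading the output: probe selection recovered the planted classifier block
(151 probes pass, including marker/pivotal genes — realistic, since
hormone-receptor probes belong in a breast-cancer classifier); two-step
k-means reproduces the planted six subtypes exactly (adjusted Rand index
1.0); the fitted ER cut-point lands within 0.07 log2 units of the planted
mixture's analytic cut; ER status is overwhelmingly unevenly distributed
across subtypes (exact Fisher p ≈ 10⁻⁵³, the same order as a real cohort of
this size and imbalance); and the subtypes differ in metastasis-free
survival (log-rank p ≈ 8×10⁻⁴).

A command-line interface mirrors the library
(`subtypeforge simulate|preprocess|select-probes|subtype|classify|markers|
risk|fisher|survival|run`); `subtypeforge run --config pipeline.yaml`
executes the whole chain and writes a JSON/CSV report bundle.

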
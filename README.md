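# bonemet

Molecular subtyping of prostate-cancer bone metastases from bulk gene
expression, as a reusable, testable pipeline.

## The problem

Bone metastasis is the lethal end stage of prostate cancer. Metastases are
molecularly heterogeneous: some retain a luminal, androgen-receptor-driven
phenotype (high *KLK3*/PSA, glandular differentiation), others are
dedifferentiated and highly proliferative (cell-cycle/DNA-damage programs,
high Ki67), and a third group is dominated by stroma–epithelial interaction
signatures. These subtypes — here called MetA, MetB and MetC — differ in
prognosis after androgen-deprivation therapy (ADT), so recognizing them
matters for treatment selection. `bonemet` implements the full analysis
chain needed to define and use such subtypes:

1. **preprocess** — combine two expression cohorts: detection filter
   (signal > 2× mean background in ≥ 1 sample), per-cohort quantile
   normalization, probe→gene collapse by highest median, per-probe
   mean-centering within each cohort (removes additive batch effects
   exactly), inner-join merge; median-scaling mode for cross-technology
   merges.
2. **discover** — PCA with sevenfold element-wise cross-validation (R² and
   Q² per component), then unsupervised clustering: the reference solution
   is Ward/Euclidean on the first two PC scores cut at *k* = 3, with
   robustness measured by re-clustering (Ward/Manhattan, k-means,
   self-organizing map, affinity propagation; 2 or 5 PCs or all genes) and
   the *preservation* statistic — the fraction of samples keeping their
   cluster under an optimal one-to-one cluster matching.
3. **classify** — per-subtype marker panels (one-vs-rest Mann–Whitney *U*,
   linear-scale median fold change ≥ 1.5, top 20 by ascending *p*) feeding
   an OPLS-DA model that predicts dummy-coded class values ŷ ∈ ℝ³;
   membership uses the 0.35/0.65 rule (ŷ > 0.65 in one class and < 0.35 in
   the others ⇒ member; any ŷ ∈ [0.35, 0.65] ⇒ intermediate; all < 0.35 ⇒
   unassigned).
4. **ihc** — immunoreactivity score IR = distribution bin (0–4) ×
   intensity grade (0–3) ∈ [0, 12], and the combinatory PSA/Ki67
   prognostic grouping (PSA IR dichotomized strictly above the cohort
   median; Ki67 fraction at/above the cohort upper quartile).
5. **survival_stats** — Kaplan–Meier with cause-specific censoring,
   log-rank, Cox proportional hazards (Breslow ties, Wald CIs), and the
   nonparametric group-test battery (Kruskal–Wallis gate → pairwise
   Mann–Whitney, Wilcoxon, Spearman, chi-square).
6. **enrich** — hypergeometric over-representation against user-supplied
   GMT gene sets and upstream-regulator over-connectivity on a directed
   interaction network, with Benjamini–Hochberg FDR control.
7. **synth** — a synthetic-cohort generator that plants the exact
   structure the analysis assumes (subtype marker blocks, additive batch
   offsets, subtype-specific exponential survival, negatively correlated
   PSA-IR/Ki67 through a calibrated Gaussian copula), so every stage is
   testable without any data download.

## Worked example

```python
from bonemet import (generate_cohort, center_probes, discover_subtypes,
                     select_markers, fit_oplsda, predict_class)
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(seed=7)            # n=72, planted 51/12/9 subtypes
centered = center_probes(cohort.expression)
solution = discover_subtypes(centered, m_components=2, k=3, seed=7)

print("cluster sizes:", solution.reference_labels.value_counts().to_dict())
print("ARI vs planted truth:",
      round(adjusted_rand_score(cohort.truth_labels, solution.reference_labels), 3))
print("k-means (all genes) preservation:", solution.preservation["kmeans@all_genes"])

panel = select_markers(centered, solution.reference_labels)
model = fit_oplsda(centered.values.loc[panel.union].T, solution.reference_labels)
calls = predict_class(model, centered.values.loc[panel.union].T)
print("call frequencies:", calls["call"].value_counts().to_dict())
```

prints

```
cluster sizes: {'A': 51, 'B': 12, 'C': 9}
ARI vs planted truth: 1.0
k-means (all genes) preservation: 1.0
call frequencies: {'A': 51, 'B': 12, 'C': 9}
```

i.e. discovery recovers the three planted subtypes perfectly (adjusted
Rand index 1.0) at the planted 71/17/12 % proportions, the all-gene
k-means re-clustering preserves 100 % of the grouping, and the OPLS-DA
classifier re-assigns every training sample to its own subtype with no
intermediate calls. Survival separation is best shown at a larger
simulated cohort, where group medians are stable:

```python
from bonemet import SynthConfig, generate_expression, generate_clinical, \
                    km_estimate, logrank

cfg = SynthConfig(n_samples=600, n_genes=30, n_markers_per_subtype=5, seed=7)
_, labels = generate_expression(cfg)
clin = generate_clinical(cfg, labels)
b = clin["subtype"] == "B"
km_b = km_estimate(clin.loc[b, "time_months"], clin.loc[b, "event"])
km_rest = km_estimate(clin.loc[~b, "time_months"], clin.loc[~b, "event"])
print("median survival, B vs rest (months):",
      round(km_b.median, 1), "vs", round(km_rest.median, 1))
```

prints `median survival, B vs rest (months): 20.9 vs 49.9` (log-rank
p = 1.2e-09), reflecting the planted 25- vs 49-month subtype medians.

A thin CLI mirrors the stages (`bonemet synth`, `bonemet preprocess`,
`bonemet discover`, `bonemet classify fit/predict`, `bonemet ihc`,
`bonemet enrich`); run `bonemet --help`.

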
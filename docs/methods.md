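# Methods

This note records the statistical models and procedures implemented in
`bonemet`, the defaults and the reasoning behind them, and what the
synthetic-data tests do and do not establish about real cohorts.

## Preprocessing model

Expression is modeled on the log2 scale as

  x_gij = μ_g + β_gb(j) + δ_g·1[j ∈ subtype(g)] + ε_gij,

with a per-gene baseline μ_g, an **additive per-probe batch offset**
β_gb, subtype marker shifts δ_g and i.i.d. Gaussian noise. Under this
model, mean-centering every probe *within each cohort* removes the batch
term exactly — which is why centering is done per cohort and the cohorts
are concatenated afterwards; a single global centering would leave
between-cohort offsets intact. Quantile normalization is likewise
computed within each cohort ("arrays normalized individually" is read as
per-study normalization), before merging.

Choices and conventions:

- **Detection filter.** A probe is kept when its signal exceeds
  `background_factor` (default 2.0) × the cohort's *mean* background in at
  least one sample of at least one cohort. The study-wide mean background
  is the default; per-sample background comparison is available via
  `per_sample_background=True`. Requiring detection in *every* cohort is
  available via `require="all"`. The filter refuses to run without
  background values rather than silently passing everything.
- **Quantile normalization.** Every column is mapped onto the mean of the
  order statistics; tied values receive the average of the reference
  values at their tied ranks (average fractional ranks, linearly
  interpolated into the reference). The operation is idempotent.
- **Scale detection.** Values with a maximum above 50 are treated as
  linear-scale intensities and log2-transformed (clipped below at 1 so
  near-background signals do not produce negative logs); `force`
  overrides the heuristic.
- **Probe collapse.** One probe per gene symbol, the one with the highest
  median across samples, computed on normalized but *pre-centered* values
  (a centered row's median carries no expression-level information).
  Ties break to the lexicographically smallest probe ID; probes without a
  gene symbol are dropped and counted.
- **Cross-technology merge.** `merge_cohorts(..., mode="median_scale")`
  divides each gene by its within-cohort median before joining, the
  appropriate normalization when one cohort is sequencing-based.

## PCA and component significance

Components come from the SVD of the column-centered samples × genes
matrix. Q² per component uses element-wise sevenfold cross-validation:
on the residual after the preceding components, matrix elements are dealt
into seven diagonal-speckle folds (deterministic pattern `(i+j) mod 7`,
so results do not depend on an RNG); each fold is deleted in turn, a
one-component model is fitted by NIPALS with missing-value skipping, and
deleted elements are predicted. Q² = 1 − PRESS/SS. A component is
*significant* while Q² > 0 (threshold configurable); the count stops at
the first failure. This is a deliberately simple, documented rule —
commercial implementations use proprietary significance heuristics, so
exact component counts are not comparable across tools.

## Clustering and the preservation statistic

Five algorithms are available: Ward/Euclidean and Ward/Manhattan
hierarchical clustering (SciPy linkage), k-means (10 restarts, seeded),
a one-dimensional batch self-organizing map, and affinity propagation
(damping 0.9, preference = median similarity, 1000 iterations).

- The **SOM** is a k-unit linear grid initialized along the first
  principal component, batch-trained with a Gaussian neighborhood
  annealed from k/2 to 0.3 over 40 epochs; samples take the label of
  their nearest unit. No SOM topology is canonical for this use; the
  linear grid is the simplest arrangement whose units act as k cluster
  prototypes.
- **Affinity propagation** determines its own cluster count. When it does
  not converge, the result is flagged and labels are withheld rather than
  forced. Note that with the median-similarity preference AP typically
  converges to *many* clusters on cohort-sized data; because the
  preservation statistic matches clusters one-to-one, AP's preservation is
  then bounded near k/k_AP and is not comparable with the fixed-k
  algorithms — it is reported, but robustness claims rest on the four
  fixed-k methods.

**Preservation** between two labelings matches clusters by
maximum-agreement one-to-one assignment (Hungarian algorithm on the
contingency table) and reports the fraction of samples whose matched
labels agree; per-reference-cluster consistency uses the same matching.
Optimal assignment rather than majority voting keeps the statistic
well-defined when cluster sizes are skewed.

The reference solution is Ward/Euclidean on the first two PC scores cut
at k = 3; k is a fixed design parameter of the subtyping scheme, exposed
but not chosen by an internal criterion. Clusters are named A, B, C in
decreasing size order.

## Marker selection and OPLS-DA

Markers are **up-regulated only**: per subtype, a one-vs-rest two-sided
Mann–Whitney U test per gene, a linear-scale median fold-change filter
(subtype over rest; on log2 data computed as 2^(Δ median), which equals
the ratio of back-transformed medians), threshold 1.5, then the 20
lowest-p genes (ties by descending fold change, then gene ID).

The classifier is a **single multi-class OPLS-DA** on the union of the
per-subtype panels (≤ 60 genes), with Y the n × 3 dummy matrix. Each
orthogonal component is extracted from a one-component PLS fit on the
current X: the part of its X-loading lying outside the span of the
Y-predictive weight space is Y-uncorrelated systematic variation; it is
normalized, scored and deflated. The predictive part is a PLS2
regression (components = classes − 1) on the filtered X; per-component
PLS weights are computed exactly as the leading singular vector of the
cross-covariance X′Y (the NIPALS fixed point), with the sign convention
that the largest-magnitude weight entry is positive. The orthogonal
component count is selected by sevenfold sample-wise cross-validated Q²Y
over 0–3 (an automatic, documented stand-in for interactive component
selection). Constant columns are dropped with a warning and re-embedded
with zero weight.

Class calls use the 0.35/0.65 rule. A sample exceeding 0.65 for two
classes simultaneously is called *intermediate* (the same label as the
in-band case): it matches more than one profile and should not be
force-assigned. External cohorts are expected to be preprocessed and
scaled like the training data (median-scaling for cross-platform);
`predict_class` tolerates up to 10 % missing marker genes (imputed at the
training mean) and refuses beyond that.

## IHC scoring

IR = distribution bin × intensity, with bins 0 % → 0, 1–25 → 1, 26–50 → 2,
51–75 → 3, 76–100 → 4 and intensity 0–3, giving the 0–12 scale. The
combinatory PSA/Ki67 grouping uses cohort-specific cutoffs: PSA IR
**strictly above** the median is high (a value equal to the median is
low — the convention that keeps the median score itself in the low
group), and Ki67 **at or above** the upper quartile is high. The
quartile uses the type-7 linear-interpolation estimator (NumPy default);
since group membership can shift at the boundary, the estimator and both
cutoffs are explicit parameters. Degenerate cutoffs (all values equal)
warn rather than fail.

## Survival and univariate statistics

Events are cancer-specific deaths; deaths from other causes and
end-of-follow-up are censored (cause-specific analysis; competing-risks
models are out of scope). The default clock is time from first ADT.
Kaplan–Meier and the log-rank test are delegated to lifelines; the
median is the earliest time the curve reaches 0.5, undefined when it
never crosses. The Cox model uses the Breslow tie convention
(statsmodels PHReg) with Wald CIs; exploding standard errors (> 10³) are
flagged as likely separation. Mann–Whitney/Wilcoxon p values are exact
for groups of ≤ 12 without ties — the relevant regime for subtype sizes
like 12 and 9 — and use the tie-corrected normal approximation otherwise.
The Kruskal–Wallis test acts as an unadjusted omnibus gate (α = 0.05)
ahead of pairwise tests.

## Enrichment

Subtype-enriched lists: Kruskal–Wallis gate, then one-vs-rest
Mann–Whitney with Benjamini–Hochberg adjustment across genes; a gene
qualifies at adjusted p < 0.01 with a higher median in the subtype. BH
is applied to the Mann–Whitney family (adjusting the KW family instead
would make the 0.01 cut unattainable for three groups of ~10, whose
exact KW p floor times the gene count exceeds it even under complete
separation). Over-representation is the hypergeometric upper tail
against the declared universe; over-connectivity applies the same
node-level hypergeometric test to each regulator's target set (an
edge-level null would require edge multiplicities the two-column edge
list does not carry). BH is used across sets/regulators; it is standard
and conservative where proprietary rank-based adjustments are not fully
specified.

## The synthetic-data generator

Defaults encode the study conditions the pipeline is designed around:
n = 72 samples in proportions 71/17/12 % (largest-remainder
apportionment, so the planted counts are exactly 51/12/9), 1000 genes
with three 40-gene marker blocks shifted +2 log2 units in their subtype,
noise SD 0.5, two batches with per-probe offset SD 1.0, exponential
survival with medians 49/25/43 months for A/B/C, 30 % censoring
(independent exponential censoring whose rate yields that expected
fraction, keeping the KM estimator consistent), and tissue PSA-IR/Ki67
drawn from a Gaussian copula calibrated so the *observable* cohort-level
Spearman correlation is −0.32. The effect size (4 × noise SD) is set by
the requirement that discovery recover planted labels at ARI ≥ 0.9 for
n ≥ 60 — the publication-scale separation is not otherwise quantifiable —
and the copula calibration inverts the observable correlation numerically
on a fixed internal calibration draw (seed independent of the cohort
seed), because subtype mean shifts and IR-score discretization make the
closed-form bivariate-normal relation inexact.

What the generator does **not** emulate: bead-level measurement error,
probe sequence effects, intensity-dependent (non-additive) batch
distortions, correlated gene-gene structure beyond the marker blocks,
non-exponential hazards, informative censoring, and pathologist
inter-observer variability in IHC grades. Passing tests therefore show
that the pipeline is correct *under its own model assumptions* — exact
batch removal, threshold behavior, estimator calibration — not that real
cohorts will cluster this cleanly.

## Problem sizes used in tests

The bundled checks run at desk scale by design: cohorts of 72 for
discovery/classification, 600–8000 samples (30 genes) where estimator
convergence is the point (KM medians at 2000; copula Spearman at 8000),
2000 replicates for the log-rank size check, and n = 500 for Cox
recovery of a planted hazard ratio of 2.

## Known limitations

- Component-significance and orthogonal-component selection rules are
  documented simplifications; counts will differ from proprietary tools.
- The multi-class OPLS-DA shares one orthogonal filter across classes;
  three binary one-vs-rest models can behave differently on strongly
  unbalanced classes (`n_predictive`/binary decomposition left to the
  caller via per-class label vectors).
- Affinity propagation's preservation is informative only about its own
  emergent partition (see above).
- No missing-value imputation anywhere; inputs with NaNs are rejected.
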
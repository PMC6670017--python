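"""Cohort preprocessing: detection filter, quantile normalization,
per-cohort probe centering, probe->gene collapse and cohort merging.

The pipeline mirrors the standard bead-array workflow for combining two
expression studies run on different chip versions:

1. keep probes whose signal clears ``background_factor`` x the cohort's mean
   background in at least one sample (detection filter);
2. quantile-normalize the arrays within each cohort;
3. log2-transform if the input is on linear scale;
4. collapse redundant probes per gene symbol, keeping the probe with the
   highest median expression;
5. mean-center every probe within each cohort (this removes additive batch
   offsets exactly) and inner-join the cohorts on gene symbol.

For cross-technology merging (e.g. arrays with RNA-seq) a median-scaling
mode divides each gene by its within-cohort median instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, concat_samples

__all__ = [
    "filter_probes",
    "quantile_normalize",
    "log2_if_linear",
    "center_probes",
    "collapse_probes",
    "merge_cohorts",
    "preprocess_cohorts",
]

logger = logging.getLogger(__name__)

#: values above this are taken to be linear-scale intensities
LINEAR_SCALE_MAX = 50.0


def filter_probes(
    cohorts: list[ExpressionMatrix],
    background_factor: float = 2.0,
    require: str = "any",
    per_sample_background: bool = False,
) -> list[ExpressionMatrix]:
    """Detection filter against the cohort mean background level.

    A probe is detected in a cohort when at least one sample's raw signal
    exceeds ``background_factor`` times that cohort's mean background.  With
    ``require="any"`` (default) a probe is kept when detected in at least one
    cohort; ``require="all"`` demands detection in every cohort.  All cohorts
    are then restricted to the common surviving probe set (the set later used
    for merging).

    ``per_sample_background=True`` compares each sample's signal against that
    sample's own background instead of the cohort-wide mean.
    """
    if require not in ("any", "all"):
        raise ValueError("require must be 'any' or 'all'")
    detected: list[pd.Series] = []
    for em in cohorts:
        if em.background is None:
            raise ValueError(
                "detection filter needs per-sample background levels; none present"
            )
        if per_sample_background:
            thresh = background_factor * em.background.to_numpy()[None, :]
        else:
            thresh = background_factor * float(em.background.mean())
        detected.append(pd.Series((em.values.to_numpy() > thresh).any(axis=1),
                                  index=em.probe_ids))
    common = cohorts[0].probe_ids
    for em in cohorts[1:]:
        common = common.intersection(em.probe_ids)
    flags = pd.concat([d.reindex(common) for d in detected], axis=1).fillna(False)
    keep = flags.any(axis=1) if require == "any" else flags.all(axis=1)
    surviving = common[keep.to_numpy()]
    logger.info("detection filter: %d / %d common probes kept", len(surviving), len(common))
    return [em.with_values(em.values.loc[surviving]) for em in cohorts]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    After normalization the sorted values of every column equal the
    across-sample mean of the order statistics.  Ties within a column are
    assigned the average of the reference values at their tied ranks.
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values are not supported (imputation out of scope)")
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        # average fractional ranks -> linear interpolation into the reference
        ranks = rankdata(X[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, np.arange(X.shape[0]), reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)


def log2_if_linear(matrix: ExpressionMatrix, force: bool | None = None) -> ExpressionMatrix:
    """log2-transform when values look like linear-scale intensities.

    Bead-array intensities are deposited on linear scale; the heuristic is a
    column maximum above ``LINEAR_SCALE_MAX``.  ``force=True/False`` overrides
    the detection.  Values are clipped at 1 before the log to avoid negative
    output from near-background signals.
    """
    is_linear = (
        force if force is not None
        else float(matrix.values.to_numpy().max()) > LINEAR_SCALE_MAX
    )
    if not is_linear:
        return matrix
    values = np.log2(matrix.values.clip(lower=1.0))
    return matrix.with_values(values)


def center_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Mean-center each probe row within each cohort.

    With additive per-probe batch offsets, per-cohort centering removes the
    batch effect exactly: every probe has mean zero in every cohort.
    """
    values = matrix.values.copy()
    for coh in matrix.cohorts:
        cols = matrix.cohort[matrix.cohort == coh].index
        block = values.loc[:, cols]
        values.loc[:, cols] = block.sub(block.mean(axis=1), axis=0)
    return matrix.with_values(values)


def collapse_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """One row per gene: keep the probe with the highest median expression.

    Medians are computed on the (normalized, pre-centered) values passed in;
    a centered row's median carries no expression-level information, so call
    this before :func:`center_probes`.  Ties break to the lexicographically
    smallest probe ID.  Probes without a gene symbol are dropped (count
    logged).
    """
    if matrix.gene_symbols is None:
        raise ValueError("probe->gene map required for collapse")
    symbols = matrix.gene_symbols
    unmapped = int(symbols.isna().sum())
    if unmapped:
        logger.info("collapse: dropping %d probes without gene symbol", unmapped)
    medians = matrix.values.median(axis=1)
    table = pd.DataFrame({"gene": symbols, "median": medians}).dropna(subset=["gene"])
    # highest median wins; ties -> smallest probe ID
    table = table.reset_index(names="probe").sort_values(
        ["gene", "median", "probe"], ascending=[True, False, True]
    )
    chosen = table.groupby("gene", sort=True).first()["probe"]
    values = matrix.values.loc[chosen.to_numpy()]
    values.index = pd.Index(chosen.index, name="gene")
    out = matrix.with_values(values)
    out.gene_symbols = pd.Series(values.index, index=values.index)
    return out


def merge_cohorts(
    a: ExpressionMatrix, b: ExpressionMatrix, mode: str = "join"
) -> ExpressionMatrix:
    """Inner-join two gene-level matrices on gene symbol.

    ``mode="join"`` concatenates the (already centered) cohorts directly.
    ``mode="median_scale"`` divides each gene's values by its within-cohort
    median before joining — the cross-technology variant used when one cohort
    is RNA-seq.
    """
    shared = a.values.index.intersection(b.values.index)
    if len(shared) == 0:
        raise ValueError("cohorts share no gene symbols; cannot merge")
    a = a.with_values(a.values.loc[shared])
    b = b.with_values(b.values.loc[shared])
    if mode == "median_scale":
        a = a.with_values(a.values.div(a.values.median(axis=1), axis=0))
        b = b.with_values(b.values.div(b.values.median(axis=1), axis=0))
    elif mode != "join":
        raise ValueError("mode must be 'join' or 'median_scale'")
    return concat_samples(a, b)


def preprocess_cohorts(
    cohorts: list[ExpressionMatrix],
    background_factor: float = 2.0,
    merge_mode: str = "join",
    log2: bool | None = None,
) -> ExpressionMatrix:
    """Full preprocessing pipeline on raw cohort matrices.

    Runs the detection filter (when backgrounds are present), per-cohort
    quantile normalization, scale detection, probe collapse, per-cohort
    centering and the cohort merge, in that order.
    """
    if any(em.background is not None for em in cohorts):
        cohorts = filter_probes(cohorts, background_factor=background_factor)
    out = []
    for em in cohorts:
        em = quantile_normalize(em)
        em = log2_if_linear(em, force=log2)
        if em.gene_symbols is not None:
            em = collapse_probes(em)
        em = center_probes(em)
        out.append(em)
    merged = out[0]
    for em in out[1:]:
        merged = merge_cohorts(merged, em, mode=merge_mode)
    return merged
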
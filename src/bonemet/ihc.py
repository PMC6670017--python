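"""Immunoreactivity (IR) scoring and the combinatory PSA/Ki67 grouping.

Pathologist-style inputs: for AR/PSA staining, the percentage of stained
tumor epithelial cells (binned 0: 0%, 1: 1-25%, 2: 26-50%, 3: 51-75%,
4: 76-100%) and the staining intensity (0 negative, 1 weak, 2 moderate,
3 intense).  The IR score is the product of the two, range 0-12.

The combinatory prognostic grouping dichotomizes tissue PSA IR at the
cohort median (strictly above -> high) and the Ki67-positive fraction at
the cohort upper quartile (>= Q3 -> high), yielding four groups; in
cohorts where PSA and Ki67 are inversely correlated the double-high group
is expected to be the rarest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "distribution_bin",
    "ir_score",
    "CombinatoryGroup",
    "combinatory_score",
    "GROUP_NAMES",
]

GROUP_NAMES = (
    "highPSA_lowKi67",
    "lowPSA_lowKi67",
    "lowPSA_highKi67",
    "highPSA_highKi67",
)


def distribution_bin(distribution_pct) -> np.ndarray | int:
    """Map stained-cell percentage to the 0-4 distribution score.

    Bins: 0% -> 0, 1-25% -> 1, 26-50% -> 2, 51-75% -> 3, 76-100% -> 4.
    """
    pct = np.asarray(distribution_pct, dtype=float)
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("distribution percentage outside [0, 100]")
    bins = np.select(
        [pct == 0, pct <= 25, pct <= 50, pct <= 75],
        [0, 1, 2, 3],
        default=4,
    )
    return bins if bins.ndim else int(bins)


def ir_score(distribution_pct, intensity) -> np.ndarray | int:
    """IR score = distribution bin (0-4) x intensity grade (0-3), range 0-12."""
    inten = np.asarray(intensity)
    if np.any((inten < 0) | (inten > 3) | (inten != np.round(inten))):
        raise ValueError("intensity must be an integer grade in {0, 1, 2, 3}")
    score = np.asarray(distribution_bin(distribution_pct)) * inten.astype(int)
    return score if score.ndim else int(score)


@dataclass(frozen=True)
class CombinatoryGroup:
    """One sample's dichotomized PSA/Ki67 status and resulting group."""

    psa_high: bool
    ki67_high: bool

    @property
    def group(self) -> str:
        return (
            f"{'high' if self.psa_high else 'low'}PSA_"
            f"{'high' if self.ki67_high else 'low'}Ki67"
        )


def combinatory_score(
    psa_ir,
    ki67_pct,
    psa_cutoff: float | None = None,
    ki67_cutoff: float | None = None,
) -> pd.DataFrame:
    """Assign each sample to one of four PSA/Ki67 prognostic groups.

    Cutoffs default to cohort-specific values computed from the input:
    the PSA IR median (strictly above -> high) and the Ki67 upper quartile
    (type-7 linear-interpolation estimator; >= Q3 -> high).  Pass explicit
    cutoffs to score a new cohort against reference values.

    Returns a DataFrame with boolean ``psa_high``/``ki67_high`` columns, the
    ``group`` name, and the cutoffs used in ``.attrs``; ``.attrs["frequencies"]``
    holds the group frequency table (fractions summing to 1).
    """
    psa = pd.Series(np.asarray(psa_ir, dtype=float))
    ki67 = pd.Series(np.asarray(ki67_pct, dtype=float))
    if len(psa) != len(ki67):
        raise ValueError("PSA and Ki67 vectors must have equal length")
    estimate_cutoffs = psa_cutoff is None or ki67_cutoff is None
    if estimate_cutoffs:
        if len(psa) < 4:
            raise ValueError("need >= 4 samples to estimate cohort cutoffs")
        if psa.nunique() == 1 or ki67.nunique() == 1:
            import warnings

            warnings.warn("degenerate cutoff: all values identical", stacklevel=2)
    if psa_cutoff is None:
        psa_cutoff = float(psa.median())
    if ki67_cutoff is None:
        ki67_cutoff = float(np.quantile(ki67, 0.75))  # type-7 default
    psa_high = psa > psa_cutoff          # "above median" is strict
    ki67_high = ki67 >= ki67_cutoff      # "upper quartile" is inclusive
    group = np.where(
        psa_high,
        np.where(ki67_high, GROUP_NAMES[3], GROUP_NAMES[0]),
        np.where(ki67_high, GROUP_NAMES[2], GROUP_NAMES[1]),
    )
    out = pd.DataFrame(
        {"psa_high": psa_high, "ki67_high": ki67_high, "group": group}
    )
    out.attrs["psa_cutoff"] = psa_cutoff
    out.attrs["ki67_cutoff"] = ki67_cutoff
    freq = out["group"].value_counts(normalize=True).reindex(GROUP_NAMES, fill_value=0.0)
    out.attrs["frequencies"] = freq
    return out
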
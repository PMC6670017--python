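"""Expression-matrix container shared across the pipeline.

An :class:`ExpressionMatrix` holds a probes/genes x samples table together
with the per-sample cohort (batch) labels, an optional probe->gene symbol
map and an optional per-sample mean background level (bead-array platforms
report one).  Values are expected on log2 scale after normalization;
the preprocessing helpers detect and transform linear-scale input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes/probes x samples expression table with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe or gene identifier, one column per sample.
    cohort
        Per-sample cohort/batch label, aligned to ``values.columns``.  A
        scalar string is broadcast to all samples.
    gene_symbols
        Optional probe->gene symbol map (Series indexed by probe ID).  Becomes
        the identity after probe collapse.
    background
        Optional per-sample mean background signal (linear scale), required
        by the detection filter.
    """

    values: pd.DataFrame
    cohort: pd.Series | str = "cohort1"
    gene_symbols: pd.Series | None = None
    background: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if isinstance(self.cohort, str):
            self.cohort = pd.Series(self.cohort, index=self.values.columns)
        self.cohort = self.cohort.reindex(self.values.columns)
        if self.cohort.isna().any():
            raise ValueError("every sample needs a cohort label")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated sample IDs: {dups}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated probe/gene IDs")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)
        if self.background is not None:
            self.background = self.background.reindex(self.values.columns)

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def cohorts(self) -> list[str]:
        """Distinct cohort labels in order of first appearance."""
        return list(dict.fromkeys(self.cohort))

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Copy of self with a new value table (annotations re-aligned)."""
        return ExpressionMatrix(
            values=values,
            cohort=self.cohort.reindex(values.columns),
            gene_symbols=(
                None if self.gene_symbols is None
                else self.gene_symbols.reindex(values.index)
            ),
            background=(
                None if self.background is None
                else self.background.reindex(values.columns)
            ),
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[:, list(sample_ids)])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column the row ID, header = sample IDs."""
        self.values.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        cohort: str = "cohort1",
        probe_map: str | Path | None = None,
        background: str | Path | None = None,
    ) -> "ExpressionMatrix":
        """Read a TSV expression table (first column = probe/gene ID).

        ``probe_map`` is a 2-column TSV (probe ID, gene symbol) and
        ``background`` a 2-column TSV (sample ID, mean background).
        """
        values = pd.read_csv(path, sep="\t", index_col=0)
        symbols = None
        if probe_map is not None:
            pm = pd.read_csv(probe_map, sep="\t", index_col=0)
            symbols = pm.iloc[:, 0]
        bg = None
        if background is not None:
            bgt = pd.read_csv(background, sep="\t", index_col=0)
            bg = bgt.iloc[:, 0].astype(float)
        return cls(values=values, cohort=cohort, gene_symbols=symbols, background=bg)


def concat_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-wise concatenation of two matrices sharing a row index."""
    if not a.values.index.equals(b.values.index):
        raise ValueError("row indices differ; merge on gene symbol first")
    values = pd.concat([a.values, b.values], axis=1)
    cohort = pd.concat([a.cohort, b.cohort])
    bg = None
    if a.background is not None and b.background is not None:
        bg = pd.concat([a.background, b.background])
    return ExpressionMatrix(
        values=values, cohort=cohort, gene_symbols=a.gene_symbols, background=bg
    )
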
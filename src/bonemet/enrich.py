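"""Gene-set over-representation and network over-connectivity analysis.

Replaces a proprietary pathway ontology with user-supplied gene-set
collections (GMT format) and directed interaction networks (two-column
edge lists).  Subtype-specific input lists come from a Kruskal-Wallis
omnibus test across clusters followed by one-vs-rest Mann-Whitney tests
with Benjamini-Hochberg adjustment (FDR < 0.01 by default), keeping genes
whose median is higher in the subtype.

Over-representation of a query list in a set uses the hypergeometric upper
tail against the declared gene universe; over-connectivity tests each
candidate upstream regulator's target set the same way, ranking putative
subtype drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "GeneSetCollection",
    "InteractionNetwork",
    "read_gmt",
    "write_gmt",
    "subtype_upregulated",
    "overrepresentation",
    "overconnectivity",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR-adjusted p values (delegates to statsmodels)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# containers and GMT / edge-list I/O
# ----------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        cleaned = {}
        for name, genes in self.sets.items():
            inter = set(genes) & self.universe
            dropped = len(set(genes)) - len(inter)
            if dropped:
                logger.info("set %s: %d genes outside universe dropped", name, dropped)
            if inter:
                cleaned[name] = inter
        self.sets = cleaned
        if not self.sets:
            raise ValueError("no non-empty gene sets after universe intersection")


@dataclass
class InteractionNetwork:
    """Directed regulator -> target edges."""

    edges: pd.DataFrame  # columns: regulator, target
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        self.edges = self.edges.rename(
            columns=dict(zip(self.edges.columns[:2], ["regulator", "target"]))
        )
        if not self.allow_self_loops:
            self.edges = self.edges[
                self.edges["regulator"] != self.edges["target"]
            ].reset_index(drop=True)

    def targets(self, regulator: str) -> set[str]:
        return set(self.edges.loc[self.edges["regulator"] == regulator, "target"])

    @property
    def regulators(self) -> list[str]:
        return list(pd.unique(self.edges["regulator"]))

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "InteractionNetwork":
        return cls(pd.read_csv(path, sep="\t", header=None, comment="#"), **kw)


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...; tab-separated).

    Without an explicit universe, the union of all set genes is used.
    """
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + sorted(genes))
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# subtype-enriched gene lists
# ----------------------------------------------------------------------

def subtype_upregulated(
    matrix: ExpressionMatrix | pd.DataFrame,
    labels,
    fdr: float = 0.01,
    gate_alpha: float = 0.05,
) -> dict[str, list[str]]:
    """Genes significantly up-regulated in each cluster versus the rest.

    Per gene: a Kruskal-Wallis omnibus test across all clusters screens at
    ``gate_alpha`` (unadjusted), then one-vs-rest two-sided Mann-Whitney
    p values are Benjamini-Hochberg adjusted across genes; a gene enters a
    subtype's list when it passes the gate, its adjusted Mann-Whitney p is
    below ``fdr`` and its median expression is higher in that subtype.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    y = pd.Series(np.asarray(labels), index=values.columns)
    classes = sorted(y.unique())
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    X = values.to_numpy(dtype=float)
    masks = {cls: (y == cls).to_numpy() for cls in classes}

    kw_p = np.ones(X.shape[0])
    for g in range(X.shape[0]):
        samples = [X[g, m] for m in masks.values()]
        if all(np.all(s == samples[0][0]) for s in samples):
            continue
        kw_p[g] = stats.kruskal(*samples).pvalue
    kw_gate = kw_p < gate_alpha

    out: dict[str, list[str]] = {}
    for cls in classes:
        m = masks[cls]
        a, b = X[:, m], X[:, ~m]
        mw_p = np.ones(X.shape[0])
        for g in range(X.shape[0]):
            if np.all(a[g] == a[g][0]) and np.all(b[g] == a[g][0]):
                continue
            mw_p[g] = stats.mannwhitneyu(a[g], b[g], alternative="two-sided").pvalue
        mw_adj = benjamini_hochberg(mw_p)
        up = np.median(a, axis=1) > np.median(b, axis=1)
        keep = kw_gate & (mw_adj < fdr) & up
        out[str(cls)] = list(values.index[keep])
    return out


# ----------------------------------------------------------------------
# over-representation and over-connectivity
# ----------------------------------------------------------------------

def _hypergeom_tail(overlap: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_size, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def overrepresentation(query, sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    The query is intersected with the universe (dropped genes logged); per
    set, the upper-tail hypergeometric probability of the observed overlap
    is computed and Benjamini-Hochberg adjusted across sets.  Sorted by
    ascending p.
    """
    q = set(query)
    if not q:
        raise ValueError("empty query")
    dropped = len(q - sets.universe)
    if dropped:
        logger.info("query: %d genes outside universe dropped", dropped)
    q &= sets.universe
    if not q:
        raise ValueError("query has no genes inside the universe")
    M = len(sets.universe)
    rows = []
    for name, genes in sets.sets.items():
        k = len(q & genes)
        rows.append(
            {
                "set": name,
                "set_size": len(genes),
                "query_size": len(q),
                "overlap": k,
                "p_value": _hypergeom_tail(k, M, len(genes), len(q)),
            }
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = benjamini_hochberg(table["p_value"])
    return table.sort_values(["p_value", "set"]).reset_index(drop=True)


def overconnectivity(
    query, network: InteractionNetwork, universe=None
) -> pd.DataFrame:
    """Rank candidate upstream regulators by target enrichment in the query.

    For each regulator, its targets (restricted to the universe; default:
    all network nodes) are tested for over-representation in the query by
    the node-hypergeometric model — the connectivity ratio of actual to
    expected interactions with the query.  Regulators without targets in the
    universe are skipped.  Sorted by ascending p (ties by descending
    overlap, then name).
    """
    if universe is None:
        universe = set(network.edges["regulator"]) | set(network.edges["target"])
    universe = set(universe)
    q = set(query) & universe
    if not q:
        raise ValueError("query has no genes inside the universe")
    M = len(universe)
    rows = []
    for reg in network.regulators:
        targets = network.targets(reg) & universe
        if not targets:
            continue
        k = len(targets & q)
        expected = len(targets) * len(q) / M
        rows.append(
            {
                "regulator": reg,
                "n_targets": len(targets),
                "overlap": k,
                "expected": expected,
                "connectivity_ratio": k / expected if expected > 0 else np.nan,
                "p_value": _hypergeom_tail(k, M, len(targets), len(q)),
            }
        )
    if not rows:
        raise ValueError("no regulator has targets inside the universe")
    table = pd.DataFrame(rows)
    table["adjusted_p"] = benjamini_hochberg(table["p_value"])
    return table.sort_values(
        ["p_value", "overlap", "regulator"], ascending=[True, False, True]
    ).reset_index(drop=True)
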
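"""Unsupervised subtype discovery: PCA with cross-validated component
significance, five clustering algorithms, and the grouping-preservation
consensus statistic.

The reference solution is Ward/Euclidean hierarchical clustering of the
first two principal-component scores cut at k = 3; robustness is judged by
re-clustering with alternative algorithms (Ward/Manhattan, k-means, a
self-organizing map, affinity propagation) and alternative input spaces
(2 or 5 components, or all genes), and reporting the fraction of samples
whose cluster membership is preserved under an optimal one-to-one cluster
matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.cluster import AffinityPropagation, KMeans
from sklearn.exceptions import ConvergenceWarning

from .matrix import ExpressionMatrix

__all__ = [
    "PcaModel",
    "ClusterResult",
    "ClusterSolution",
    "fit_pca",
    "cluster",
    "preservation",
    "preservation_per_cluster",
    "discover_subtypes",
    "ALGORITHMS",
]

ALGORITHMS = ("ward_euclidean", "ward_manhattan", "kmeans", "som", "affinity_propagation")


# ----------------------------------------------------------------------
# PCA with sevenfold element-wise cross-validation
# ----------------------------------------------------------------------

@dataclass
class PcaModel:
    """Principal-component model with cross-validated significance.

    ``r2_per_component`` are the explained-variance fractions; ``q2_per_component``
    the cross-validated predictive fractions from sevenfold element-wise
    deletion; ``n_significant`` counts the leading components with Q2 above
    the threshold.
    """

    loadings: pd.DataFrame       # genes x components
    scores: pd.DataFrame         # samples x components
    r2_per_component: np.ndarray
    q2_per_component: np.ndarray
    n_significant: int
    mean_: pd.Series             # per-gene training mean

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _nipals_component_missing(
    E: np.ndarray, missing: np.ndarray, max_iter: int = 500, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """One principal component of E by NIPALS, skipping missing elements.

    Returns (t, p) with unit-norm loading p; the reconstruction of a deleted
    element is ``t[i] * p[j]``.
    """
    obs = (~missing).astype(float)
    X0 = np.where(missing, 0.0, E)
    j0 = int(np.argmax((X0**2).sum(axis=0)))
    t = X0[:, j0].copy()
    if not np.any(t):
        t = obs[:, j0].copy()
    for _ in range(max_iter):
        denom = t**2 @ obs
        denom[denom == 0] = 1.0
        p = (t @ X0) / denom
        norm = np.linalg.norm(p)
        if norm == 0:
            break
        p /= norm
        denom_t = obs @ p**2
        denom_t[denom_t == 0] = 1.0
        t_new = (X0 @ p) / denom_t
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-30):
            t = t_new
            break
        t = t_new
    return t, p


def fit_pca(
    matrix: ExpressionMatrix | pd.DataFrame,
    max_components: int = 10,
    n_folds: int = 7,
    q2_threshold: float = 0.0,
) -> PcaModel:
    """Singular-value decomposition of the centered samples x genes table.

    Q2 per component follows the element-wise deletion scheme: working on the
    residual after the preceding components, matrix elements are dealt into
    ``n_folds`` diagonal-speckle groups; each group in turn is treated as
    missing, a one-component model is fitted to the remainder and the deleted
    elements are predicted.  ``Q2 = 1 - PRESS / SS(residual)``.
    ``n_significant`` is the number of leading components with Q2 above
    ``q2_threshold``.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    X = values.T.to_numpy(dtype=float)  # samples x genes
    sample_ids, gene_ids = values.columns, values.index
    mean = X.mean(axis=0)
    Xc = X - mean
    n, p = Xc.shape
    a_max = min(max_components, n - 1 if n > 1 else 1, p)

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_ss = float((Xc**2).sum())
    r2 = (s**2 / total_ss)[:a_max] if total_ss > 0 else np.zeros(a_max)
    scores = (U * s)[:, :a_max]
    loadings = Vt[:a_max].T

    # deterministic diagonal speckle: element (i, j) -> fold (i + j) mod n_folds
    ii, jj = np.indices((n, p))
    folds = (ii + jj) % n_folds
    q2 = np.zeros(a_max)
    E = Xc.copy()
    for a in range(a_max):
        ss = float((E**2).sum())
        if ss <= 0:
            break
        press = 0.0
        for f in range(n_folds):
            mask = folds == f
            t, pl = _nipals_component_missing(E, mask)
            press += float(((E - np.outer(t, pl))[mask] ** 2).sum())
        q2[a] = 1.0 - press / ss
        E -= np.outer(scores[:, a], loadings[:, a])

    n_sig = 0
    while n_sig < a_max and q2[n_sig] > q2_threshold:
        n_sig += 1

    comp_ids = [f"PC{i + 1}" for i in range(a_max)]
    return PcaModel(
        loadings=pd.DataFrame(loadings, index=gene_ids, columns=comp_ids),
        scores=pd.DataFrame(scores, index=sample_ids, columns=comp_ids),
        r2_per_component=r2,
        q2_per_component=q2,
        n_significant=n_sig,
        mean_=pd.Series(mean, index=gene_ids),
    )


# ----------------------------------------------------------------------
# clustering algorithms
# ----------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Labels plus convergence status (affinity propagation may fail)."""

    labels: np.ndarray | None
    converged: bool
    k: int
    algorithm: str


def _som_labels(X: np.ndarray, k: int, seed: int, n_iter: int = 40) -> np.ndarray:
    """Batch-trained one-dimensional self-organizing map with k units.

    Prototypes start spread along the first principal component; the
    neighborhood is Gaussian on the unit grid with a width annealed from
    k/2 down to 0.3; after training, samples are labeled by nearest unit.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    center = X.mean(axis=0)
    Xc = X - center
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = Xc @ Vt[0]
    span = np.linspace(pc1.min(), pc1.max(), k)
    prototypes = center + span[:, None] * Vt[0][None, :]
    prototypes = prototypes + rng.normal(0, 1e-8, prototypes.shape)  # tie break
    grid = np.arange(k, dtype=float)
    for it in range(n_iter):
        sigma = (k / 2.0) * (0.3 / (k / 2.0)) ** (it / max(n_iter - 1, 1))
        d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        h = np.exp(-((grid[None, :] - grid[bmu][:, None]) ** 2) / (2 * sigma**2))
        denom = h.sum(axis=0)
        keep = denom > 1e-12
        prototypes[keep] = (h.T @ X)[keep] / denom[keep, None]
    d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def cluster(
    data: np.ndarray | pd.DataFrame,
    algorithm: str,
    k: int | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster samples (rows) with one of the five configured algorithms.

    ``k`` is required for every algorithm except affinity propagation, whose
    cluster count is emergent; AP non-convergence is reported as a flagged
    result (``labels=None``) rather than forced labels.
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if algorithm != "affinity_propagation":
        if k is None:
            raise ValueError(f"{algorithm} requires k")
        if k > n:
            raise ValueError("k cannot exceed the number of samples")

    if algorithm == "ward_euclidean":
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    elif algorithm == "ward_manhattan":
        Z = linkage(pdist(X, metric="cityblock"), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    elif algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
    elif algorithm == "som":
        raw = _som_labels(X, k, seed)
        # compress to 0..k_used-1 in order of appearance
        _, labels = np.unique(raw, return_inverse=True)
    else:  # affinity_propagation
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ap = AffinityPropagation(
                    damping=0.9, max_iter=1000, random_state=seed
                ).fit(X)
            except ConvergenceWarning:
                return ClusterResult(None, False, 0, algorithm)
        if len(ap.cluster_centers_indices_) == 0:
            return ClusterResult(None, False, 0, algorithm)
        labels = ap.labels_
        return ClusterResult(labels, True, len(np.unique(labels)), algorithm)
    return ClusterResult(np.asarray(labels), True, len(np.unique(labels)), algorithm)


# ----------------------------------------------------------------------
# preservation (consensus) statistic
# ----------------------------------------------------------------------

def _match_clusters(reference, alternative) -> dict:
    """Optimal one-to-one cluster matching by maximum agreement."""
    ref = pd.Series(reference).astype(str).to_numpy()
    alt = pd.Series(alternative).astype(str).to_numpy()
    if len(ref) != len(alt):
        raise ValueError("label vectors differ in length")
    table = pd.crosstab(pd.Series(ref), pd.Series(alt))
    rows, cols = linear_sum_assignment(table.to_numpy(), maximize=True)
    return {
        "table": table,
        "pairs": [(table.index[r], table.columns[c]) for r, c in zip(rows, cols)],
        "ref": ref,
        "alt": alt,
    }


def preservation(reference, alternative) -> float:
    """Fraction of samples keeping their cluster under optimal matching.

    Clusters of the two labelings are paired by maximum-agreement one-to-one
    assignment on the contingency table (Hungarian algorithm); the statistic
    is the fraction of samples whose alternative cluster is the one matched
    to their reference cluster.  Invariant to relabeling of either argument.
    """
    m = _match_clusters(reference, alternative)
    agree = sum(int(m["table"].loc[r, c]) for r, c in m["pairs"])
    return agree / len(m["ref"])


def preservation_per_cluster(reference, alternative) -> dict[str, float]:
    """Per-reference-cluster consistency under the same optimal matching."""
    m = _match_clusters(reference, alternative)
    mapping = dict(m["pairs"])
    out = {}
    for r in m["table"].index:
        members = m["ref"] == r
        if r in mapping:
            out[r] = float(np.mean(m["alt"][members] == mapping[r]))
        else:
            out[r] = 0.0
    return out


# ----------------------------------------------------------------------
# subtype discovery pipeline
# ----------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """Reference subtype labels plus alternative labelings and preservation."""

    reference_labels: pd.Series                 # per-sample subtype A/B/C/...
    alternative_labels: dict[str, np.ndarray | None] = field(default_factory=dict)
    preservation: dict[str, float] = field(default_factory=dict)
    converged: dict[str, bool] = field(default_factory=dict)
    k: int = 3
    input_space: str = "pc_scores(2)"
    pca: PcaModel | None = None

    def __post_init__(self) -> None:
        for name, lab in self.alternative_labels.items():
            if lab is not None and len(lab) != len(self.reference_labels):
                raise ValueError(f"label vector length mismatch for {name}")
        for name, v in self.preservation.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"preservation out of [0,1] for {name}")


def _subtype_names(labels: np.ndarray, k: int) -> pd.Series:
    """Rename integer clusters to letters by decreasing size (A largest)."""
    counts = pd.Series(labels).value_counts()
    letters = [chr(ord("A") + i) for i in range(k)]
    mapping = {c: letters[i] for i, c in enumerate(counts.index)}
    return pd.Series(labels).map(mapping)


def discover_subtypes(
    matrix: ExpressionMatrix | pd.DataFrame,
    m_components: int = 2,
    k: int = 3,
    seed: int = 0,
    algorithms: tuple[str, ...] = ALGORITHMS,
    alt_spaces: tuple[str, ...] = ("pc_scores(2)", "pc_scores(5)", "all_genes"),
    max_components: int = 10,
) -> ClusterSolution:
    """Discover k molecular subtypes and assess their robustness.

    The reference labeling is Ward/Euclidean on the first ``m_components``
    PC scores (defaults follow the design: 2 components, k = 3), with
    clusters named A, B, C... by decreasing size.  Every configured
    algorithm/input-space combination is re-run and its preservation against
    the reference recorded; affinity propagation is recorded as
    non-converged when it fails.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    pca = fit_pca(matrix, max_components=max(max_components, m_components, 5))
    scores = pca.scores.to_numpy()
    all_genes = values.T.to_numpy(dtype=float)

    ref = cluster(scores[:, :m_components], "ward_euclidean", k=k, seed=seed)
    reference = _subtype_names(ref.labels, k)
    reference.index = values.columns

    spaces = {}
    for sp in alt_spaces:
        if sp == "all_genes":
            spaces[sp] = all_genes
        elif sp.startswith("pc_scores("):
            m = int(sp[len("pc_scores("):-1])
            spaces[sp] = scores[:, : min(m, scores.shape[1])]
        else:
            raise ValueError(f"unknown input space {sp!r}")

    solution = ClusterSolution(
        reference_labels=reference,
        k=k,
        input_space=f"pc_scores({m_components})",
        pca=pca,
    )
    for sp, data in spaces.items():
        for algo in algorithms:
            if algo == "ward_euclidean" and sp == f"pc_scores({m_components})":
                pass  # the reference itself; still recorded (preservation 1.0)
            res = cluster(data, algo, k=None if algo == "affinity_propagation" else k,
                          seed=seed)
            name = f"{algo}@{sp}"
            solution.converged[name] = res.converged
            solution.alternative_labels[name] = res.labels
            if res.labels is not None:
                solution.preservation[name] = preservation(reference, res.labels)
    return solution
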
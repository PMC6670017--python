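"""Marker-panel selection and the OPLS-DA subtype classifier.

Markers: per subtype, a one-vs-rest two-sided Mann-Whitney U test per gene
combined with a linear-scale median fold-change filter (subtype over rest,
>= 1.5 by default); the top 20 lowest-p up-regulated genes form the panel.

Classifier: orthogonal projections to latent structures discriminant
analysis (OPLS-DA).  Class membership Y is dummy-coded (one 0/1 column per
subtype); orthogonal components capture systematic X-variation uncorrelated
with Y and are removed before a PLS regression on the filtered X.  Predicted
class values are interpreted with the 0.35/0.65 rule: a sample belongs to a
class when that class's predicted value exceeds 0.65 and all others fall
below 0.35; any value inside [0.35, 0.65] marks the sample intermediate;
all values below 0.35 leave it unassigned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .matrix import ExpressionMatrix

__all__ = [
    "MarkerPanel",
    "OplsdaModel",
    "select_markers",
    "fit_oplsda",
    "predict_class",
    "external_validation",
]

LOWER_THRESHOLD = 0.35
UPPER_THRESHOLD = 0.65


# ----------------------------------------------------------------------
# marker selection
# ----------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """Per-subtype ranked lists of up-regulated marker genes.

    ``tables`` maps subtype -> DataFrame with columns (gene, p_value,
    fold_change), sorted by ascending p (ties broken by descending fold
    change, then gene ID).
    """

    tables: dict[str, pd.DataFrame]
    panel_size: int = 20

    @property
    def union(self) -> list[str]:
        """All panel genes, deduplicated, in subtype order."""
        seen: dict[str, None] = {}
        for t in self.tables.values():
            for g in t["gene"]:
                seen.setdefault(g, None)
        return list(seen)

    def genes(self, subtype: str) -> list[str]:
        return list(self.tables[subtype]["gene"])


def select_markers(
    matrix: ExpressionMatrix | pd.DataFrame,
    labels,
    n_top: int = 20,
    fc_min: float = 1.5,
    logged: bool = True,
) -> MarkerPanel:
    """Select each subtype's top up-regulated marker genes.

    For every gene and subtype, a two-sided Mann-Whitney U test compares the
    subtype's samples against all others.  The fold change is the ratio of
    group medians on the linear scale; with ``logged=True`` (log2 input,
    the default) it is computed as ``2 ** (median_in - median_rest)``, which
    equals the ratio of back-transformed medians.  Genes with fold change
    >= ``fc_min`` are ranked by ascending p value and the top ``n_top`` kept.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    y = pd.Series(np.asarray(labels), index=values.columns)
    classes = sorted(y.unique())
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")

    X = values.to_numpy(dtype=float)
    tables: dict[str, pd.DataFrame] = {}
    for cls in classes:
        in_cls = (y == cls).to_numpy()
        a, b = X[:, in_cls], X[:, ~in_cls]
        med_in, med_rest = np.median(a, axis=1), np.median(b, axis=1)
        if logged:
            fc = 2.0 ** (med_in - med_rest)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                fc = np.where(med_rest != 0, med_in / med_rest, np.inf)
                fc = np.where((med_rest == 0) & (med_in == 0), 1.0, fc)
        pvals = np.ones(X.shape[0])
        for g in range(X.shape[0]):
            if np.all(a[g] == a[g][0]) and np.all(b[g] == a[g][0]):
                pvals[g] = 1.0  # constant gene: no evidence
                continue
            pvals[g] = mannwhitneyu(a[g], b[g], alternative="two-sided").pvalue
        table = pd.DataFrame(
            {"gene": values.index, "p_value": pvals, "fold_change": fc}
        )
        table = table[table["fold_change"] >= fc_min]
        table = table.sort_values(
            ["p_value", "fold_change", "gene"], ascending=[True, False, True]
        ).head(n_top).reset_index(drop=True)
        tables[str(cls)] = table
    return MarkerPanel(tables=tables, panel_size=n_top)


# ----------------------------------------------------------------------
# OPLS-DA
# ----------------------------------------------------------------------

def _pls_nipals(
    X: np.ndarray, Y: np.ndarray, n_components: int
) -> dict[str, np.ndarray]:
    """Two-block PLS (PLS2) with NIPALS-style deflation on centered X, Y.

    Per component the X-weight is the leading left singular vector of the
    cross-covariance ``X' Y`` (the fixed point of the NIPALS inner power
    iteration, computed exactly); scores, loadings and the rank-one
    deflation follow the NIPALS recursion.  Returns weights W, X-loadings
    P, Y-weights C and the regression coefficient matrix
    ``B = W (P'W)^-1 C'`` such that ``Y_hat = X B``.
    """
    Xr, Yr = X.copy(), Y.copy()
    n, p = X.shape
    q = Y.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    used = 0
    for a in range(n_components):
        U_, s_, _ = np.linalg.svd(Xr.T @ Yr, full_matrices=False)
        if s_[0] <= 1e-14 * max(1.0, s_.sum()):
            break
        w = U_[:, 0]
        # fix the sign for determinism: largest-|coefficient| entry positive
        w = w * np.sign(w[np.argmax(np.abs(w))])
        t = Xr @ w
        tt = t @ t
        if tt == 0:
            break
        p_load = Xr.T @ t / tt
        c = Yr.T @ t / tt
        Xr -= np.outer(t, p_load)
        Yr -= np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_load, c, t
        used += 1
    W, P, C, T = W[:, :used], P[:, :used], C[:, :used], T[:, :used]
    if used == 0:
        return {"W": W, "P": P, "C": C, "T": T, "B": np.zeros((p, q))}
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return {"W": W, "P": P, "C": C, "T": T, "B": B}


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA model predicting dummy-coded class values.

    ``w_ortho``/``p_ortho`` define the orthogonal-variation filter applied
    before the predictive PLS regression with coefficients ``coef``.
    """

    classes: list[str]
    gene_order: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    w_ortho: np.ndarray          # genes x n_orthogonal
    p_ortho: np.ndarray
    coef: np.ndarray             # genes x n_classes
    n_orthogonal: int
    n_predictive: int
    lower: float = LOWER_THRESHOLD
    upper: float = UPPER_THRESHOLD
    r2y: float = float("nan")
    scores_pred: np.ndarray | None = None   # training predictive scores
    scores_ortho: np.ndarray | None = None  # training orthogonal scores

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper < 1.0:
            raise ValueError("thresholds must satisfy 0 < lower < upper < 1")

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "gene_order": self.gene_order,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "w_ortho": self.w_ortho.tolist(),
            "p_ortho": self.p_ortho.tolist(),
            "coef": self.coef.tolist(),
            "n_orthogonal": self.n_orthogonal,
            "n_predictive": self.n_predictive,
            "lower": self.lower,
            "upper": self.upper,
            "r2y": self.r2y,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "OplsdaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=d["classes"],
            gene_order=d["gene_order"],
            x_mean=np.asarray(d["x_mean"]),
            y_mean=np.asarray(d["y_mean"]),
            w_ortho=np.asarray(d["w_ortho"]).reshape(len(d["gene_order"]), -1),
            p_ortho=np.asarray(d["p_ortho"]).reshape(len(d["gene_order"]), -1),
            coef=np.asarray(d["coef"]),
            n_orthogonal=d["n_orthogonal"],
            n_predictive=d["n_predictive"],
            lower=d["lower"],
            upper=d["upper"],
            r2y=d["r2y"],
        )

    # -- prediction ------------------------------------------------------
    def predict_values(self, X_new: np.ndarray) -> np.ndarray:
        """Predicted class-value 3-vectors for centered-scale new samples."""
        Xc = np.asarray(X_new, dtype=float) - self.x_mean
        for a in range(self.n_orthogonal):
            t_o = Xc @ self.w_ortho[:, a]
            Xc = Xc - np.outer(t_o, self.p_ortho[:, a])
        return Xc @ self.coef + self.y_mean


def _dummy_matrix(labels, classes: list[str]) -> np.ndarray:
    y = np.asarray(labels)
    return np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y])


def _fit_opls_core(
    X: np.ndarray, Y: np.ndarray, n_orthogonal: int, n_predictive: int
) -> dict:
    """Orthogonal filtering followed by a predictive PLS regression.

    Each orthogonal component is extracted from the loading of a one-component
    PLS fit: the part of that loading lying outside the span of the
    Y-predictive weight space is systematic variation uncorrelated with Y and
    is deflated from X before refitting.
    """
    Xr = X.copy()
    p = X.shape[1]
    w_o = np.zeros((p, n_orthogonal))
    p_o = np.zeros((p, n_orthogonal))
    used = 0
    for _ in range(n_orthogonal):
        # orthonormal basis of the Y-predictive weight space of current Xr
        Wy = np.column_stack(
            [Xr.T @ Y[:, j] for j in range(Y.shape[1])]
        )
        Wy, _ = np.linalg.qr(Wy)
        comp = _pls_nipals(Xr, Y, 1)
        load = comp["P"][:, 0]
        w = load - Wy @ (Wy.T @ load)
        nw = np.linalg.norm(w)
        if nw < 1e-10:
            break
        w /= nw
        t = Xr @ w
        pl = Xr.T @ t / (t @ t)
        Xr -= np.outer(t, pl)
        w_o[:, used], p_o[:, used] = w, pl
        used += 1
    pls = _pls_nipals(Xr, Y, n_predictive)
    ss_res = float(((Y - Xr @ pls["B"]) ** 2).sum())
    ss_tot = float((Y**2).sum())
    return {
        "w_ortho": w_o[:, :used],
        "p_ortho": p_o[:, :used],
        "coef": pls["B"],
        "scores_pred": pls["T"],
        "n_orthogonal": used,
        "r2y": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "Xr": Xr,
    }


def _cv_q2y(X: np.ndarray, Y: np.ndarray, n_orthogonal: int,
            n_predictive: int, n_folds: int = 7) -> float:
    """Sample-wise k-fold cross-validated Q2Y for a given component count."""
    n = X.shape[0]
    folds = np.arange(n) % n_folds
    press, ss = 0.0, float(((Y - Y.mean(axis=0)) ** 2).sum())
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        xm, ym = X[tr].mean(axis=0), Y[tr].mean(axis=0)
        core = _fit_opls_core(X[tr] - xm, Y[tr] - ym, n_orthogonal, n_predictive)
        Xc = X[te] - xm
        for a in range(core["n_orthogonal"]):
            t_o = Xc @ core["w_ortho"][:, a]
            Xc = Xc - np.outer(t_o, core["p_ortho"][:, a])
        press += float(((Y[te] - (Xc @ core["coef"] + ym)) ** 2).sum())
    return 1.0 - press / ss


def fit_oplsda(
    X: pd.DataFrame | np.ndarray,
    labels,
    n_orthogonal: int | None = None,
    n_predictive: int | None = None,
    max_orthogonal: int = 3,
) -> OplsdaModel:
    """Fit the OPLS-DA subtype classifier on samples x markers data.

    Y is the dummy (0/1) class matrix; X is column-centered internally.
    With ``n_orthogonal=None`` the orthogonal component count is chosen by
    sevenfold cross-validated Q2Y over 0..``max_orthogonal``.  The predictive
    part defaults to ``n_classes - 1`` PLS components.  Constant columns are
    dropped with a warning (their coefficient is fixed at zero).
    """
    if isinstance(X, pd.DataFrame):
        genes = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        genes = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(labels)
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    Y = _dummy_matrix(y, [str(c) for c in classes])
    if n_predictive is None:
        n_predictive = len(classes) - 1

    keep = Xm.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant column(s)", stacklevel=2
        )
    x_mean_full = Xm.mean(axis=0)
    Xk = Xm[:, keep]
    Xc = Xk - Xk.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    if n_orthogonal is None:
        q2 = [
            _cv_q2y(Xk, Y, q, n_predictive)
            for q in range(0, max_orthogonal + 1)
        ]
        n_orthogonal = int(np.argmax(q2))

    core = _fit_opls_core(Xc, Yc, n_orthogonal, n_predictive)

    # re-embed dropped constant columns with zero weight
    p_full = Xm.shape[1]

    def embed(M: np.ndarray) -> np.ndarray:
        out = np.zeros((p_full, M.shape[1]))
        out[keep] = M
        return out

    scores_ortho = (
        Xc @ core["w_ortho"] if core["n_orthogonal"] else np.zeros((Xm.shape[0], 0))
    )
    return OplsdaModel(
        classes=[str(c) for c in classes],
        gene_order=genes,
        x_mean=x_mean_full,
        y_mean=y_mean,
        w_ortho=embed(core["w_ortho"]),
        p_ortho=embed(core["p_ortho"]),
        coef=embed(core["coef"]),
        n_orthogonal=core["n_orthogonal"],
        n_predictive=n_predictive,
        r2y=core["r2y"],
        scores_pred=core["scores_pred"],
        scores_ortho=scores_ortho,
    )


# ----------------------------------------------------------------------
# class calls
# ----------------------------------------------------------------------

def _call_one(values: np.ndarray, lower: float, upper: float) -> str:
    above = values > upper
    in_band = (values >= lower) & (values <= upper)
    if above.sum() == 1 and (values < lower).sum() == len(values) - 1:
        return "member"
    if above.sum() > 1:
        return "intermediate"  # matches two classes simultaneously; flagged
    if in_band.any():
        return "intermediate"
    return "unassigned"


def predict_class(
    model: OplsdaModel,
    X_new: pd.DataFrame | np.ndarray,
    max_missing: float = 0.10,
) -> pd.DataFrame:
    """Predict class values and apply the 0.35/0.65 membership rule.

    A DataFrame input is re-aligned to the training gene order; genes missing
    beyond ``max_missing`` raise, otherwise missing genes are imputed at the
    training mean.  Returns per-sample predicted values (one column per
    class) plus a ``call`` column in {A, B, C, ..., intermediate, unassigned}.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [g for g in model.gene_order if g not in X_new.columns]
        if len(missing) > max_missing * len(model.gene_order):
            raise ValueError(
                f"{len(missing)}/{len(model.gene_order)} marker genes missing "
                f"(> {max_missing:.0%} allowed)"
            )
        X_al = X_new.reindex(columns=model.gene_order)
        for g in missing:
            X_al[g] = model.x_mean[model.gene_order.index(g)]
        index = X_new.index
        Xm = X_al.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        index = pd.RangeIndex(Xm.shape[0])
    values = model.predict_values(Xm)
    out = pd.DataFrame(values, columns=model.classes, index=index)
    calls = []
    for i in range(values.shape[0]):
        status = _call_one(values[i], model.lower, model.upper)
        if status == "member":
            calls.append(model.classes[int(np.argmax(values[i]))])
        else:
            calls.append(status)
    out["call"] = calls
    return out


def external_validation(
    model: OplsdaModel,
    panel: MarkerPanel,
    cohort: ExpressionMatrix | pd.DataFrame,
) -> dict:
    """Predict an external cohort and report class frequencies.

    The cohort (genes x samples, preprocessed and scaled as the training
    data) is classified; the report carries per-class counts and fractions,
    the intermediate/unassigned fractions, and, per subtype, the median
    pairwise Spearman correlation of that subtype's panel genes within the
    new cohort (markers of a real subtype should co-vary there too).
    """
    values = cohort.values if isinstance(cohort, ExpressionMatrix) else cohort
    calls = predict_class(model, values.T)
    counts = calls["call"].value_counts()
    n = len(calls)
    marker_corr: dict[str, float] = {}
    for subtype, table in panel.tables.items():
        genes = [g for g in table["gene"] if g in values.index]
        if len(genes) >= 2:
            sub = values.loc[genes].T
            rho = spearmanr(sub).statistic
            if np.ndim(rho) == 2:
                iu = np.triu_indices(len(genes), k=1)
                rho = float(np.median(np.asarray(rho)[iu]))
            marker_corr[subtype] = float(rho)
    return {
        "n": n,
        "counts": counts.to_dict(),
        "frequencies": (counts / n).to_dict(),
        "fraction_intermediate": float((calls["call"] == "intermediate").mean()),
        "fraction_unassigned": float((calls["call"] == "unassigned").mean()),
        "calls": calls,
        "marker_correlation": marker_corr,
    }
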
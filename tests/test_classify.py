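"""Marker selection (exact rank-test oracle) and the OPLS-DA classifier
(PLS oracle, threshold rule, external validation)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from bonemet import (
    center_probes,
    external_validation,
    fit_oplsda,
    generate_cohort,
    predict_class,
    select_markers,
)
from bonemet.classify import OplsdaModel, _dummy_matrix


# ----------------------------------------------------------------------
# marker selection
# ----------------------------------------------------------------------

def _exact_mw_two_sided(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of rank splits."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    obs_u = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for comb in itertools.combinations(range(n + m), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us, dtype=float)
    p_greater = np.mean(us >= obs_u)
    p_less = np.mean(us <= obs_u)
    return min(1.0, 2 * min(p_greater, p_less))


def test_exact_mw_p_matches_enumeration_on_3v3():
    """The gene p-value equals full enumeration over all 20 rank splits."""
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([4.0, 5.0, 6.0])
    values = pd.DataFrame(
        [np.concatenate([x, y])], index=["g1"],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = ["in"] * 3 + ["out"] * 3
    panel = select_markers(values, labels, n_top=5, fc_min=0.0)
    got = panel.tables["out"].set_index("gene").loc["g1", "p_value"]
    assert got == pytest.approx(_exact_mw_two_sided(y, x))
    assert got == pytest.approx(2 / 20)  # most extreme split, doubled


def test_constant_gene_excluded_by_fold_change():
    values = pd.DataFrame(
        [[5.0] * 6, [1, 1, 1, 4, 4, 4]], index=["flat", "up"],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = ["a"] * 3 + ["b"] * 3
    panel = select_markers(values, labels, n_top=5)
    assert "flat" not in set(panel.tables["b"]["gene"])
    assert "up" in set(panel.tables["b"]["gene"])


def test_panel_size_capped_at_n_top(centered_matrix, default_cohort):
    panel = select_markers(centered_matrix, default_cohort.truth_labels, n_top=20)
    for table in panel.tables.values():
        assert len(table) == 20
        assert table["p_value"].is_monotonic_increasing
        assert (table["fold_change"] >= 1.5).all()
        assert table["gene"].is_unique


def test_markers_are_the_planted_blocks(marker_panel):
    from bonemet import SynthConfig, marker_blocks

    blocks = marker_blocks(SynthConfig())
    for s in "ABC":
        assert set(marker_panel.genes(s)) <= set(blocks[s])


def test_pvalues_invariant_to_monotone_transform_but_fc_not(rng):
    values = pd.DataFrame(
        rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(8)],
    )
    values.iloc[0, :4] += 3.0
    labels = ["a"] * 4 + ["b"] * 4
    before = select_markers(values, labels, n_top=10, fc_min=0.0)
    transformed = values * 2.0 + 1.0  # monotone per-gene map
    after = select_markers(transformed, labels, n_top=10, fc_min=0.0)
    a = before.tables["a"].set_index("gene")
    b = after.tables["a"].set_index("gene")
    shared = a.index.intersection(b.index)
    np.testing.assert_allclose(a.loc[shared, "p_value"], b.loc[shared, "p_value"])
    assert not np.allclose(a.loc[shared, "fold_change"], b.loc[shared, "fold_change"])


def test_small_class_rejected():
    values = pd.DataFrame(np.ones((3, 4)), columns=list("wxyz"))
    with pytest.raises(ValueError, match="fewer than 2"):
        select_markers(values, ["a", "b", "b", "b"])


# ----------------------------------------------------------------------
# OPLS-DA
# ----------------------------------------------------------------------

def test_dummy_matrix_columns_sum_to_class_sizes():
    y = list("AABBBC")
    Y = _dummy_matrix(y, ["A", "B", "C"])
    np.testing.assert_allclose(Y.sum(axis=0), [2, 3, 1])
    np.testing.assert_allclose(Y.sum(axis=1), 1.0)


def test_zero_orthogonal_equals_pls_oracle(rng):
    """With no orthogonal filtering the model is PLS-DA; predictions match
    an independent NIPALS PLS implementation to 1e-8."""
    X = rng.normal(size=(40, 12))
    y = rng.choice(list("ABC"), size=40)
    model = fit_oplsda(X, y, n_orthogonal=0, n_predictive=2)
    Y = _dummy_matrix(y, ["A", "B", "C"])
    # sklearn's stopping rule is on the squared weight change, so tol must be
    # the square of the accuracy the comparison needs
    oracle = PLSRegression(n_components=2, scale=False, tol=1e-25, max_iter=10000).fit(X, Y)
    np.testing.assert_allclose(
        model.predict_values(X), oracle.predict(X), atol=1e-8
    )


def test_separable_training_data_respects_thresholds(fitted_model, centered_matrix,
                                                     marker_panel, default_cohort):
    X = centered_matrix.values.loc[marker_panel.union].T
    calls = predict_class(fitted_model, X)
    own = [
        calls.loc[s, str(lab)] for s, lab in default_cohort.truth_labels.items()
    ]
    assert np.mean(np.asarray(own) > 0.65) >= 0.95
    others = [
        calls.loc[s, c]
        for s, lab in default_cohort.truth_labels.items()
        for c in "ABC" if c != lab
    ]
    assert np.mean(np.asarray(others) < 0.35) >= 0.95


@pytest.mark.parametrize(
    "values,expected",
    [
        ((0.9, 0.05, 0.05), "A"),
        ((0.05, 0.9, 0.05), "B"),
        ((0.5, 0.5, 0.0), "intermediate"),
        ((0.2, 0.2, 0.2), "unassigned"),
        ((0.9, 0.9, 0.1), "intermediate"),  # two simultaneous memberships
    ],
)
def test_threshold_rule(values, expected, fitted_model):
    from bonemet.classify import _call_one

    call = _call_one(np.asarray(values), fitted_model.lower, fitted_model.upper)
    if expected in ("intermediate", "unassigned"):
        assert call == expected
    else:
        assert call == "member"


def test_r2y_nondecreasing_in_orthogonal_components(centered_matrix, marker_panel,
                                                    default_cohort):
    X = centered_matrix.values.loc[marker_panel.union].T
    r2 = [
        fit_oplsda(X, default_cohort.truth_labels, n_orthogonal=q).r2y
        for q in range(3)
    ]
    assert all(r2[i + 1] >= r2[i] - 1e-9 for i in range(len(r2) - 1))


def test_predictive_scores_orthogonal_to_orthogonal_scores(rng):
    X = rng.normal(size=(30, 20))
    X[:, :5] += rng.normal(size=(30, 1)) * 2  # structured Y-unrelated variation
    y = rng.choice(list("AB"), size=30)
    model = fit_oplsda(X, y, n_orthogonal=2, n_predictive=1)
    if model.scores_ortho.shape[1]:
        cross = model.scores_pred.T @ model.scores_ortho
        norm = (
            np.linalg.norm(model.scores_pred, axis=0)[:, None]
            * np.linalg.norm(model.scores_ortho, axis=0)[None, :]
        )
        assert np.abs(cross / norm).max() < 1e-6


def test_constant_columns_dropped_with_warning(rng):
    X = rng.normal(size=(20, 5))
    X[:, 2] = 7.0
    y = rng.choice(list("AB"), size=20)
    with pytest.warns(UserWarning, match="constant"):
        model = fit_oplsda(X, y, n_orthogonal=0)
    assert model.coef[2].tolist() == [0.0, 0.0]


def test_model_json_roundtrip(tmp_path, fitted_model, centered_matrix, marker_panel):
    path = tmp_path / "model.json"
    fitted_model.to_json(path)
    loaded = OplsdaModel.from_json(path)
    X = centered_matrix.values.loc[marker_panel.union].T
    np.testing.assert_allclose(
        loaded.predict_values(X.to_numpy()),
        fitted_model.predict_values(X.to_numpy()),
        atol=1e-12,
    )


def test_missing_marker_genes_beyond_fraction_rejected(fitted_model, centered_matrix,
                                                       marker_panel):
    X = centered_matrix.values.loc[marker_panel.union].T
    dropped = X.drop(columns=X.columns[:12])  # 20% of 60 markers
    with pytest.raises(ValueError, match="missing"):
        predict_class(fitted_model, dropped)


# ----------------------------------------------------------------------
# external validation
# ----------------------------------------------------------------------

def test_validation_on_training_cohort_reproduces_frequencies(
    fitted_model, marker_panel, centered_matrix, default_cohort
):
    report = external_validation(fitted_model, marker_panel, centered_matrix)
    counts = default_cohort.truth_labels.value_counts()
    for s in "ABC":
        assert report["counts"].get(s, 0) == counts[s]


def test_second_batch_frequencies_within_binomial_error(fitted_model, marker_panel):
    cohort_b = generate_cohort(seed=77)
    from bonemet import center_probes

    em = center_probes(cohort_b.expression)
    report = external_validation(fitted_model, marker_panel, em)
    n = report["n"]
    for s, p in zip("ABC", (0.71, 0.17, 0.12)):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(report["frequencies"].get(s, 0.0) - p) <= 3 * se + report[
            "fraction_intermediate"
        ]
    assert report["marker_correlation"]["A"] > 0.2  # markers co-vary in new cohort


def test_planted_mixtures_called_intermediate(fitted_model, marker_panel,
                                              centered_matrix, default_cohort):
    """Samples blending the A and B profiles mostly land in the
    intermediate band."""
    X = centered_matrix.values.loc[marker_panel.union]
    a_cols = default_cohort.truth_labels[default_cohort.truth_labels == "A"].index[:8]
    b_cols = default_cohort.truth_labels[default_cohort.truth_labels == "B"].index[:8]
    mixed = (X[a_cols].to_numpy() + X[b_cols].to_numpy()) / 2.0
    mixed_df = pd.DataFrame(
        mixed.T, columns=X.index, index=[f"mix{i}" for i in range(8)]
    )
    calls = predict_class(fitted_model, mixed_df)
    assert (calls["call"] == "intermediate").mean() >= 0.75
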
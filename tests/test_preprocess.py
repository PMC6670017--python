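"""Preprocessing: detection filter, quantile normalization, centering,
probe collapse and cohort merging, each against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonemet import (
    ExpressionMatrix,
    center_probes,
    collapse_probes,
    filter_probes,
    merge_cohorts,
    quantile_normalize,
)
from bonemet.preprocess import log2_if_linear, preprocess_cohorts


def _em(values, cohort="c1", **kw):
    df = pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(np.shape(values)[0])],
        columns=[f"{cohort}_s{j}" for j in range(np.shape(values)[1])],
    )
    return ExpressionMatrix(df, cohort=cohort, **kw)


class TestFilterProbes:
    def test_requires_background(self):
        with pytest.raises(ValueError, match="background"):
            filter_probes([_em([[1.0, 2.0]])])

    def test_probe_below_threshold_everywhere_removed(self):
        bg = pd.Series([10.0, 10.0], index=["c1_s0", "c1_s1"])
        em = _em([[5.0, 8.0], [25.0, 3.0]], background=bg)
        (out,) = filter_probes([em])
        assert list(out.probe_ids) == ["p1"]  # 25 > 2*10; probe p0 never exceeds

    def test_detection_in_one_cohort_is_enough(self):
        """A probe over threshold in a single sample of one cohort is kept."""
        bg = pd.Series(10.0, index=["c1_s0", "c1_s1"])
        a = _em([[30.0, 1.0], [1.0, 1.0]], cohort="c1", background=bg)
        bg2 = pd.Series(10.0, index=["c2_s0", "c2_s1"])
        b = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["p0", "p1"],
                         columns=["c2_s0", "c2_s1"]),
            cohort="c2", background=bg2,
        )
        out_a, out_b = filter_probes([a, b])
        assert list(out_a.probe_ids) == ["p0"]
        assert list(out_b.probe_ids) == ["p0"]

    def test_ten_probe_toy_matches_enumeration(self, rng):
        """Surviving set equals brute-force application of the rule."""
        signals = {f"c{c}": rng.uniform(0, 50, size=(10, 3)) for c in (1, 2)}
        bgs = {"c1": 8.0, "c2": 12.0}
        ems = []
        for c in ("c1", "c2"):
            cols = [f"{c}_s{j}" for j in range(3)]
            ems.append(ExpressionMatrix(
                pd.DataFrame(signals[c], index=[f"p{i}" for i in range(10)], columns=cols),
                cohort=c,
                background=pd.Series(bgs[c], index=cols),
            ))
        expected = [
            f"p{i}" for i in range(10)
            if (signals["c1"][i] > 2 * bgs["c1"]).any()
            or (signals["c2"][i] > 2 * bgs["c2"]).any()
        ]
        out, _ = filter_probes(ems)
        assert list(out.probe_ids) == expected


class TestQuantileNormalize:
    def test_two_column_forced_result(self):
        em = _em([[1.0, 2.0], [3.0, 4.0]])
        out = quantile_normalize(em)
        np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_unchanged(self):
        em = _em([[1.0, 1.0], [7.0, 7.0], [3.0, 3.0]])
        out = quantile_normalize(em)
        np.testing.assert_allclose(out.values.to_numpy(), em.values.to_numpy())

    def test_column_order_statistics_identical(self, rng):
        em = _em(rng.normal(size=(5, 4)))
        out = quantile_normalize(em).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        em = _em(rng.normal(size=(8, 5)))
        once = quantile_normalize(em)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12
        )

    def test_missing_values_rejected(self):
        em = _em([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(em)

    def test_ties_get_average_reference(self):
        # column 0 has a tie at ranks 1-2; each tied value gets the average
        # of the reference values at those ranks
        em = _em([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        out = quantile_normalize(em).values.to_numpy()
        ref = np.array([1.0, 1.5, 4.0])  # mean of sorted columns
        assert out[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)


class TestCenterProbes:
    def test_simple_row(self):
        em = _em([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(
            center_probes(em).values.to_numpy(), [[-1.0, 0.0, 1.0]]
        )

    def test_constant_row_becomes_zero(self):
        em = _em([[4.0, 4.0, 4.0]])
        np.testing.assert_allclose(center_probes(em).values.to_numpy(), 0.0)

    def test_planted_batch_offsets_removed_exactly(self, rng):
        """Per-cohort centering removes additive per-probe offsets to
        machine precision: per-probe cohort means agree across cohorts."""
        base = rng.normal(size=(20, 6))
        offsets = rng.normal(scale=3.0, size=(20, 1))
        values = np.concatenate([base[:, :3], base[:, 3:] + offsets], axis=1)
        cols = [f"a{j}" for j in range(3)] + [f"b{j}" for j in range(3)]
        em = ExpressionMatrix(
            pd.DataFrame(values, index=[f"p{i}" for i in range(20)], columns=cols),
            cohort=pd.Series(["A"] * 3 + ["B"] * 3, index=cols),
        )
        out = center_probes(em).values.to_numpy()
        np.testing.assert_allclose(out[:, :3].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out[:, 3:].mean(axis=1), 0.0, atol=1e-12)
        diff = out[:, :3].mean(axis=1) - out[:, 3:].mean(axis=1)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)


class TestCollapseProbes:
    def _with_map(self, values, genes):
        em = _em(values)
        em.gene_symbols = pd.Series(genes, index=em.probe_ids)
        return em

    def test_single_probe_gene_kept(self):
        em = self._with_map([[1.0, 2.0]], ["G1"])
        out = collapse_probes(em)
        assert list(out.values.index) == ["G1"]

    def test_highest_median_probe_wins(self):
        em = self._with_map([[5.0, 5.0], [7.0, 7.0]], ["G1", "G1"])
        out = collapse_probes(em)
        np.testing.assert_allclose(out.values.loc["G1"].to_numpy(), [7.0, 7.0])

    def test_tie_breaks_to_smallest_probe_id(self):
        em = self._with_map([[3.0, 3.0], [3.0, 3.0]], ["G1", "G1"])
        out = collapse_probes(em)
        # p0 < p1 lexicographically; identical rows, so check via values index
        assert out.values.shape[0] == 1

    def test_unmapped_probes_dropped(self):
        em = self._with_map([[1.0, 1.0], [2.0, 2.0]], ["G1", None])
        out = collapse_probes(em)
        assert list(out.values.index) == ["G1"]

    def test_twelve_probe_toy_matches_bruteforce(self, rng):
        values = rng.normal(size=(12, 4))
        genes = [f"G{i % 5}" for i in range(12)]
        em = self._with_map(values, genes)
        out = collapse_probes(em)
        # brute force: per gene, argmax of row medians, ties -> smallest probe id
        med = np.median(values, axis=1)
        expected = {}
        for i, g in enumerate(genes):
            if g not in expected or med[i] > med[expected[g]]:
                expected[g] = i
        for g, i in expected.items():
            np.testing.assert_allclose(out.values.loc[g].to_numpy(), values[i])
        assert out.values.shape[0] == 5


class TestMergeCohorts:
    def _gene_em(self, values, genes, cohort):
        cols = [f"{cohort}_s{j}" for j in range(np.shape(values)[1])]
        return ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=cols), cohort=cohort
        )

    def test_disjoint_gene_sets_error(self):
        a = self._gene_em([[1.0, 2.0]], ["G1"], "a")
        b = self._gene_em([[1.0, 2.0]], ["G2"], "b")
        with pytest.raises(ValueError, match="no gene symbols"):
            merge_cohorts(a, b)

    def test_median_scale_makes_cohort_medians_one(self):
        a = self._gene_em([[2.0, 4.0, 8.0], [1.0, 3.0, 5.0]], ["G1", "G2"], "a")
        b = self._gene_em([[10.0, 20.0, 40.0], [2.0, 6.0, 10.0]], ["G1", "G2"], "b")
        merged = merge_cohorts(a, b, mode="median_scale")
        for coh in ("a", "b"):
            cols = merged.cohort[merged.cohort == coh].index
            np.testing.assert_allclose(
                merged.values.loc[:, cols].median(axis=1).to_numpy(), 1.0
            )

    def test_inner_join_keeps_shared_genes_only(self):
        a = self._gene_em(np.arange(8.0).reshape(4, 2), list("WXYZ"), "a")
        b = self._gene_em(np.arange(8.0).reshape(4, 2), list("XYZQ"), "b")
        merged = merge_cohorts(a, b)
        assert sorted(merged.values.index) == ["X", "Y", "Z"]
        assert merged.n_samples == 4


def test_log2_detection_and_override():
    em = _em([[100.0, 400.0], [200.0, 800.0]])
    out = log2_if_linear(em)
    np.testing.assert_allclose(
        out.values.to_numpy(), np.log2([[100.0, 400.0], [200.0, 800.0]])
    )
    kept = log2_if_linear(em, force=False)
    np.testing.assert_allclose(kept.values.to_numpy(), em.values.to_numpy())


def test_full_pipeline_on_two_raw_cohorts(rng):
    """Raw linear cohorts with batch offsets come out merged, centered."""
    genes = [f"G{i}" for i in range(30)]
    probes = [f"p{i}" for i in range(30)]
    ems = []
    for c, shift in (("c1", 1.0), ("c2", 4.0)):
        cols = [f"{c}_s{j}" for j in range(5)]
        lin = 2 ** (rng.normal(8.0, 1.0, size=(30, 5)) + shift)
        ems.append(ExpressionMatrix(
            pd.DataFrame(lin, index=probes, columns=cols),
            cohort=c,
            gene_symbols=pd.Series(genes, index=probes),
            background=pd.Series(10.0, index=cols),
        ))
    merged = preprocess_cohorts(ems)
    assert merged.n_samples == 10
    for coh in ("c1", "c2"):
        cols = merged.cohort[merged.cohort == coh].index
        np.testing.assert_allclose(
            merged.values.loc[:, cols].mean(axis=1).to_numpy(), 0.0, atol=1e-10
        )
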
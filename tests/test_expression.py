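"""Expression calls, normalisation, and functional categorisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irminer.expression import (
    ExpressionMatrix,
    assign_category,
    call_expressed,
    classify_expression,
    condition_means,
    log2_scale_tpm,
    median_of_ratios_normalize,
    subset_sharing_counts,
    tumour_subset_expression,
)
from irminer.reference import CATEGORIES


def make_matrix(values, scale, meta_rows):
    samples = list(values.columns)
    meta = pd.DataFrame(meta_rows, index=samples, columns=["cell_type", "state"])
    return ExpressionMatrix(values=values, scale=scale, sample_meta=meta)


@pytest.fixture
def tpm_matrix():
    values = pd.DataFrame(
        {"s1": [0.0, 7.0, 1023.0], "s2": [3.0, 7.0, 15.0]},
        index=["g1", "g2", "g3"],
    )
    return make_matrix(
        values, "tpm", [("Mono", "resting"), ("Mono", "activated")]
    )


class TestScaling:
    def test_log2_tpm_values(self, tpm_matrix):
        out = log2_scale_tpm(tpm_matrix)
        assert out.scale == "log2"
        assert out.values.loc["g1", "s1"] == 0.0
        assert out.values.loc["g2", "s1"] == 3.0
        assert out.values.loc["g3", "s1"] == 10.0

    def test_wrong_scale_rejected(self, tpm_matrix):
        log2 = log2_scale_tpm(tpm_matrix)
        with pytest.raises(ValueError):
            log2_scale_tpm(log2)

    def test_negative_values_rejected(self):
        values = pd.DataFrame({"s1": [-1.0], "s2": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="negative"):
            make_matrix(values, "tpm",
                        [("M", "resting"), ("M", "activated")])


class TestMedianOfRatios:
    def test_doubled_sample_normalises_to_equal_columns(self):
        base = np.array([10.0, 50.0, 200.0, 5.0])
        values = pd.DataFrame(
            {"a": base, "b": 2 * base}, index=[f"g{i}" for i in range(4)]
        )
        m = make_matrix(values, "counts", [("M", "resting"), ("M", "activated")])
        out = median_of_ratios_normalize(m)
        assert out.scale == "log2"
        np.testing.assert_allclose(out.values["a"], out.values["b"], rtol=1e-12)

    def test_single_gene_size_factors(self):
        # counts (2, 8): geometric mean 4, ratios (0.5, 2)
        values = pd.DataFrame({"a": [2.0], "b": [8.0]}, index=["g"])
        m = make_matrix(values, "counts", [("M", "resting"), ("M", "activated")])
        out = median_of_ratios_normalize(m)
        # both columns normalise to count 4 -> log2(5)
        np.testing.assert_allclose(out.values.values, np.log2(5.0), rtol=1e-12)

    def test_all_zero_gene_ignored_but_preserved(self):
        values = pd.DataFrame(
            {"a": [0.0, 10.0], "b": [0.0, 10.0]}, index=["g0", "g1"]
        )
        m = make_matrix(values, "counts", [("M", "resting"), ("M", "activated")])
        out = median_of_ratios_normalize(m)
        assert (out.values.loc["g0"] == 0.0).all()
        assert "g0" in out.values.index

    def test_no_universally_positive_gene_rejected(self):
        values = pd.DataFrame({"a": [0.0, 5.0], "b": [5.0, 0.0]}, index=["g0", "g1"])
        m = make_matrix(values, "counts", [("M", "resting"), ("M", "activated")])
        with pytest.raises(ValueError, match="positive in every sample"):
            median_of_ratios_normalize(m)


class TestConditionMeans:
    def test_mean_over_condition_samples(self):
        values = pd.DataFrame(
            {"s1": [4.0], "s2": [6.0], "s3": [7.0]}, index=["g"]
        )
        m = make_matrix(
            values, "log2",
            [("Mono", "resting"), ("Mono", "resting"), ("Mono", "activated")],
        )
        means = condition_means(m)
        assert means.loc["g", ("Mono", "resting")] == 5.0
        assert means.loc["g", ("Mono", "activated")] == 7.0

    def test_missing_condition_absent(self):
        values = pd.DataFrame({"s1": [4.0]}, index=["g"])
        m = make_matrix(values, "log2", [("Mono", "resting")])
        means = condition_means(m)
        assert ("Mono", "resting") in means.columns
        assert ("Mono", "activated") not in means.columns


class TestCallExpressed:
    def make_means(self, gene_values):
        return pd.DataFrame(
            {("Mono", "resting"): gene_values},
            index=[f"g{i}" for i in range(len(gene_values))],
        )

    def test_strictly_above_median(self):
        all_means = self.make_means([1.0, 2.0, 3.0, 4.0, 5.0])
        out = call_expressed(all_means, all_means)
        # median is 3.0; only strictly greater values are expressed
        assert list(out[("Mono", "resting")]) == [False, False, False, True, True]

    def test_all_equal_means_none_expressed(self):
        all_means = self.make_means([2.0, 2.0, 2.0])
        assert not call_expressed(all_means, all_means).values.any()

    def test_candidate_only_universe_rejected(self):
        all_means = self.make_means([1.0, 2.0, 3.0, 4.0])
        candidates = all_means.iloc[:2]
        extra = candidates.rename(index={"g0": "x0", "g1": "x1"})
        with pytest.raises(ValueError, match="universe"):
            call_expressed(extra, candidates)


class TestAssignCategory:
    @pytest.mark.parametrize(
        "r,a,fc,expected",
        [
            (False, False, 0.0, "not_expressed"),
            (False, True, 2.0, "negative_feedback"),
            (True, True, 0.2, "threshold"),
            (True, True, 0.5, "threshold"),     # boundary -> closed interval
            (True, True, -0.5, "threshold"),
            (True, True, 0.51, "threshold_negative_feedback"),
            (True, True, -0.51, "threshold_disinhibition"),
            (True, False, -0.1, "threshold_disinhibition"),
            (True, False, 3.0, "threshold_disinhibition"),  # lost on activation
        ],
    )
    def test_category_rules(self, r, a, fc, expected):
        assert assign_category(r, a, fc) == expected

    def test_non_finite_fc_rejected(self):
        with pytest.raises(ValueError):
            assign_category(True, True, float("nan"))

    @given(
        st.booleans(), st.booleans(),
        st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True)
    def test_total_single_valued_partition(self, r, a, fc):
        assert assign_category(r, a, fc) in CATEGORIES

    def test_exactly_five_reachable_labels(self):
        grid = [
            assign_category(r, a, fc)
            for r in (False, True)
            for a in (False, True)
            for fc in (-2.0, -0.51, -0.5, 0.0, 0.5, 0.51, 2.0)
        ]
        assert set(grid) == set(CATEGORIES)


class TestClassifyAndSharing:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(5)
        genes = ["hi_flat", "lo_induced", "hi_up"] + [f"bg{i}" for i in range(60)]
        samples, meta_rows, cols = [], [], {}
        for ct in ("Mono", "NK"):
            for state in ("resting", "activated"):
                for k in range(3):
                    samples.append(f"{ct}_{state}_{k}")
                    meta_rows.append((ct, state))
        data = {}
        for s, (ct, state) in zip(samples, meta_rows):
            col = np.concatenate(
                [
                    [9.0, 1.0 if state == "resting" else 9.0,
                     9.0 if state == "resting" else 11.0],
                    rng.normal(5.0, 1.0, size=60),
                ]
            )
            data[s] = col
        values = pd.DataFrame(data, index=genes)
        meta = pd.DataFrame(meta_rows, index=samples, columns=["cell_type", "state"])
        return ExpressionMatrix(values=values, scale="log2", sample_meta=meta)

    def test_planted_patterns_recovered(self, matrix):
        calls = classify_expression(matrix, genes=["hi_flat", "lo_induced", "hi_up"])
        by = {(c.gene, c.cell_type): c.category for c in calls}
        assert by[("hi_flat", "Mono")] == "threshold"
        assert by[("lo_induced", "Mono")] == "negative_feedback"
        assert by[("hi_up", "NK")] == "threshold_negative_feedback"

    def test_per_sample_majority_mode_agrees_on_clear_genes(self, matrix):
        a = classify_expression(matrix, genes=["hi_flat"], call_mode="condition-mean")
        b = classify_expression(matrix, genes=["hi_flat"],
                                call_mode="per-sample-majority")
        assert a[0].category == b[0].category

    def test_sharing_counts_partition_expressed_genes(self, matrix):
        calls = classify_expression(matrix)
        counts = subset_sharing_counts(calls)
        expressed_genes = {
            c.gene for c in calls
            if c.expressed_resting or c.expressed_activated
        }
        assert sum(counts.values()) == len(expressed_genes)
        assert frozenset({"Mono", "NK"}) in counts  # planted genes hit both


class TestTumourSubsets:
    def make_inputs(self, cell_z, meta_rows, weights):
        cells = [f"c{i}" for i in range(len(cell_z))]
        z = pd.DataFrame({"g": cell_z}, index=cells)
        meta = pd.DataFrame(meta_rows, index=cells, columns=["subset", "subcluster"])
        return z, meta, weights

    def test_zero_mean_not_expressed(self):
        z, meta, w = self.make_inputs(
            [-1.0, 1.0], [("CD8_ex", "a"), ("CD8_ex", "a")],
            {"CD8_ex": {"a": 1.0}},
        )
        (call,) = tumour_subset_expression(z, meta, w)
        assert call.weighted_mean_z == 0.0
        assert not call.expressed

    def test_weighted_mean(self):
        z, meta, w = self.make_inputs(
            [1.0, -0.5], [("T", "a"), ("T", "b")],
            {"T": {"a": 0.5, "b": 0.5}},
        )
        (call,) = tumour_subset_expression(z, meta, w)
        assert call.weighted_mean_z == pytest.approx(0.25)
        assert call.expressed

    def test_asymmetric_weights(self):
        z, meta, w = self.make_inputs(
            [-0.1, 2.0], [("T", "a"), ("T", "b")],
            {"T": {"a": 0.9, "b": 0.1}},
        )
        (call,) = tumour_subset_expression(z, meta, w)
        assert call.weighted_mean_z == pytest.approx(0.11)
        assert call.expressed

    def test_weights_must_sum_to_one(self):
        z, meta, w = self.make_inputs(
            [1.0], [("T", "a")], {"T": {"a": 0.7}}
        )
        with pytest.raises(ValueError, match="sum"):
            tumour_subset_expression(z, meta, w)

    def test_empty_subcluster_rejected(self):
        z, meta, w = self.make_inputs(
            [1.0], [("T", "a")], {"T": {"a": 0.5, "b": 0.5}}
        )
        with pytest.raises(ValueError, match="no cells"):
            tumour_subset_expression(z, meta, w)
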
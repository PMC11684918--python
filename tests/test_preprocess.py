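import numpy as np
import pandas as pd
import pytest

from tknet import CountTable, HostTable, SampleMetadata
from tknet.tables import Scale
from tknet.preprocess import (
    aggregate_to_family,
    cumulative_abundance_filter,
    intersect_common_features,
    median_normalize_host,
    normalize_asv_pair,
    quantile_normalize,
    relativize_and_mean_normalize,
    relativize_per_million,
)
from tknet.tables import TaxonomyTable


def _ct(values, features=None, samples=None, scale=Scale.raw_counts):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountTable(pd.DataFrame(values, index=features, columns=samples), scale=scale)


class TestRelativizePerMillion:
    def test_proportional_scaling(self):
        out = relativize_per_million(_ct([[2], [3], [5]]))
        assert out.data["s0"].tolist() == [200000.0, 300000.0, 500000.0]
        assert out.scale is Scale.per_million

    def test_single_feature(self):
        out = relativize_per_million(_ct([[7.0, 3.0]]))
        assert (out.data.to_numpy() == 1_000_000.0).all()

    def test_column_sums_invariant(self):
        rng = np.random.default_rng(1)
        out = relativize_per_million(_ct(rng.integers(0, 50, size=(20, 10)) + 1.0))
        np.testing.assert_allclose(out.data.sum(axis=0), 1_000_000.0, rtol=1e-9)

    def test_zero_sample_errors(self):
        with pytest.raises(ValueError, match="s1"):
            relativize_per_million(_ct([[1.0, 0.0]]))

    def test_scale_gate(self):
        t = relativize_per_million(_ct([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="raw counts"):
            relativize_per_million(t)


class TestCumulativeAbundanceFilter:
    def test_prefix_rule(self):
        t = _ct([[9999.0], [1.0]], features=["A", "B"])
        _, kept = cumulative_abundance_filter(t, 0.9995)
        assert kept == ["A"]

    def test_equal_abundances_keep_all(self):
        t = _ct(np.ones((4, 2)))
        _, kept = cumulative_abundance_filter(t, 0.9995)
        assert len(kept) == 4

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        t = _ct(rng.pareto(1.2, size=(50, 6)) + 0.01)
        _, kept = cumulative_abundance_filter(t, 0.9)
        # oracle: scan sorted cumulative sums directly
        totals = t.data.sum(axis=1).sort_values(ascending=False)
        cum = totals.cumsum() / totals.sum()
        n_keep = int(np.searchsorted(cum.to_numpy(), 0.9 - 1e-12) + 1)
        assert kept == list(totals.index[:n_keep])

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            cumulative_abundance_filter(
                CountTable(pd.DataFrame(np.empty((0, 2)), columns=["s0", "s1"])), 0.9
            )


def test_intersect_common_features_orders_by_first_ranking():
    assert intersect_common_features(["A", "B", "C"], ["D", "C", "B"]) == ["B", "C"]
    assert intersect_common_features(["A", "B"], ["A", "B"]) == ["A", "B"]
    with pytest.warns(UserWarning, match="common"):
        assert intersect_common_features(["A"], ["B"]) == []


class TestQuantileNormalize:
    def test_hand_oracle(self):
        t = _ct([[5.0, 4.0], [2.0, 1.0], [3.0, 6.0]], scale=Scale.per_million)
        out = quantile_normalize(t)
        np.testing.assert_allclose(out.data["s0"], [5.5, 1.5, 3.5])
        np.testing.assert_allclose(out.data["s1"], [3.5, 1.5, 5.5])
        assert out.scale is Scale.quantile_normalized

    def test_identical_columns_fixed_point(self):
        t = _ct([[4.0, 4.0], [1.0, 1.0], [2.0, 2.0]], scale=Scale.per_million)
        out = quantile_normalize(t)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_output_columns_share_sorted_values(self):
        rng = np.random.default_rng(3)
        t = _ct(rng.random((30, 8)) * 100, scale=Scale.per_million)
        out = quantile_normalize(t)
        ref = np.sort(out.data.iloc[:, 0].to_numpy())
        for col in out.data.columns[1:]:
            np.testing.assert_allclose(np.sort(out.data[col].to_numpy()), ref)

    def test_ties_get_mean_of_reference_values(self):
        # s0 has a tied pair occupying ranks 1 and 2
        t = _ct([[2.0, 10.0], [2.0, 20.0], [9.0, 30.0]], scale=Scale.per_million)
        out = quantile_normalize(t)
        ref = np.sort(t.data.to_numpy(), axis=0).mean(axis=1)
        expected_tied = ref[:2].mean()
        np.testing.assert_allclose(out.data["s0"].to_numpy()[:2], expected_tied)

    def test_single_sample_identity(self):
        t = _ct([[3.0], [1.0]], scale=Scale.per_million)
        out = quantile_normalize(t)
        pd.testing.assert_frame_equal(out.data, t.data)


class TestMeanNormalize:
    def test_constant_relative_row_stays_one(self):
        out = relativize_and_mean_normalize(_ct([[1.0, 1.0, 1.0]]))
        np.testing.assert_allclose(out.data.to_numpy(), 1.0)

    def test_mean_division(self):
        out = relativize_and_mean_normalize(_ct([[2.0, 4.0], [8.0, 6.0]]))
        # columns are first relativized, then each row divided by its mean
        rel = np.array([[0.2, 0.4], [0.8, 0.6]])
        expected = rel / rel.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.data.to_numpy(), expected)

    def test_feature_means_are_one(self):
        rng = np.random.default_rng(5)
        out = relativize_and_mean_normalize(_ct(rng.integers(1, 100, size=(15, 6)).astype(float)))
        np.testing.assert_allclose(out.data.mean(axis=1), 1.0)

    def test_zero_mean_feature_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero mean"):
            out = relativize_and_mean_normalize(_ct([[0.0, 0.0], [1.0, 2.0]]))
        assert (out.data.iloc[0] == 0).all()


class TestMedianNormalizeHost:
    @staticmethod
    def _host(values, samples):
        data = pd.DataFrame(np.atleast_2d(values), index=["p1"], columns=samples)
        info = pd.DataFrame({"kind": ["phenotype"], "tissue": [""]}, index=["p1"])
        return HostTable(data, info)

    @staticmethod
    def _meta(samples, experiments):
        return SampleMetadata(
            pd.DataFrame(
                {"experiment": experiments, "group": ["WD"] * len(samples)},
                index=pd.Index(samples, name="sample_id"),
            )
        )

    def test_division_by_experiment_median(self):
        host = self._host([2.0, 4.0, 6.0], ["a", "b", "c"])
        out = median_normalize_host(host, self._meta(["a", "b", "c"], [1, 1, 1]))
        np.testing.assert_allclose(out.data.loc["p1"], [0.5, 1.0, 1.5])
        assert out.normalized

    def test_constant_parameter_becomes_ones(self):
        host = self._host([3.0, 3.0], ["a", "b"])
        out = median_normalize_host(host, self._meta(["a", "b"], [1, 1]))
        np.testing.assert_allclose(out.data.loc["p1"], 1.0)

    def test_pooled_rank_order_preserved_across_experiment_scales(self):
        # same signal on very different scales per experiment
        rng = np.random.default_rng(11)
        signal = rng.random(6) + 0.5
        vals = np.concatenate([signal * 1.0, signal * 100.0])
        samples = [f"e1s{i}" for i in range(6)] + [f"e2s{i}" for i in range(6)]
        host = self._host(vals, samples)
        meta = self._meta(samples, [1] * 6 + [2] * 6)
        out = median_normalize_host(host, meta).data.loc["p1"]
        within1 = np.argsort(out[:6].to_numpy())
        within2 = np.argsort(out[6:].to_numpy())
        np.testing.assert_array_equal(within1, within2)
        np.testing.assert_allclose(out[:6].to_numpy(), out[6:].to_numpy())

    def test_zero_median_errors(self):
        host = self._host([0.0, 0.0, 1.0], ["a", "b", "c"])
        with pytest.raises(ValueError, match="p1"):
            median_normalize_host(host, self._meta(["a", "b", "c"], [1, 1, 1]))


class TestAggregateToFamily:
    tax = TaxonomyTable(
        pd.DataFrame(
            {"family": ["Lachnospiraceae", "Lachnospiraceae", "Muribaculaceae", None]},
            index=pd.Index(["a", "b", "c", "d"], name="feature_id"),
        )
    )

    def test_additivity(self):
        t = _ct([[10.0, 5.0], [1.0, 5.0]], features=["a", "b"])
        out = aggregate_to_family(t, self.tax)
        np.testing.assert_allclose(out.data.loc["Lachnospiraceae"], [11.0, 10.0])

    def test_distinct_families_identity_up_to_relabeling(self):
        t = _ct([[1.0], [2.0]], features=["a", "c"])
        out = aggregate_to_family(t, self.tax)
        assert sorted(out.feature_ids) == ["Lachnospiraceae", "Muribaculaceae"]

    def test_column_sums_preserved_and_unassigned_bucket(self):
        t = _ct([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], features=["a", "c", "d"])
        out = aggregate_to_family(t, self.tax)
        np.testing.assert_allclose(out.data.sum(axis=0), t.data.sum(axis=0))
        assert "Unassigned" in out.feature_ids


def test_normalize_asv_pair_runs_fixed_order(default_study):
    qn, common = normalize_asv_pair(default_study.counts, threshold=0.9995)
    assert set(qn) == {1, 2}
    for t in qn.values():
        assert t.scale is Scale.quantile_normalized
        assert t.feature_ids == common
    # the filter may only drop features
    assert 0 < len(common) <= default_study.counts[1].shape[0]
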
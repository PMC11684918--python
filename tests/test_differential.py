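import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from tknet import CountTable, SampleMetadata
from tknet.differential import (
    bh_fdr,
    classify_response_groups,
    comparison_stats,
    family_differential,
    fisher_combined,
    mann_whitney_u,
    test_with_consistency as run_consistency_test,
)


def mwu_oracle(x, y, tail):
    """Exact Mann-Whitney p by exhaustive enumeration of all rank assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"

    def u_of(xs):
        return sum(1 for xi in xs for yj in pooled if yj not in xs and xi > yj)

    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n_x = len(x)
    us = [u_of(set(c)) for c in itertools.combinations(pooled, n_x)]
    us = np.array(us)
    if tail == "greater":
        p = np.mean(us >= u_obs)
    elif tail == "less":
        p = np.mean(us <= u_obs)
    else:
        p = min(1.0, 2 * min(np.mean(us >= u_obs), np.mean(us <= u_obs)))
    return u_obs, p


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, tail, u_exp, p_exp",
        [
            ([1, 2], [3, 4], "two", 0.0, 2 / 6),
            ([1, 4], [2, 3], "two", 2.0, 1.0),
            ([5, 6, 7], [1, 2, 3], "greater", 9.0, 1 / 20),
        ],
    )
    def test_worked_examples(self, x, y, tail, u_exp, p_exp):
        u, p = mann_whitney_u(x, y, tail)
        assert u == u_exp
        assert p == pytest.approx(p_exp)

    def test_exact_matches_enumeration_all_small_sizes(self):
        """Exhaustive-oracle sweep over every group-size pair up to 5."""
        rng = np.random.default_rng(42)
        for n_x in range(1, 6):
            for n_y in range(1, 6):
                vals = rng.permutation(np.arange(1, n_x + n_y + 1, dtype=float))
                x, y = vals[:n_x], vals[n_x:]
                for tail in ("two", "greater", "less"):
                    u, p = mann_whitney_u(x, y, tail)
                    u_o, p_o = mwu_oracle(x, y, tail)
                    assert u == u_o
                    assert p == pytest.approx(p_o, abs=1e-12), (n_x, n_y, tail)

    def test_tie_handling_counts_half(self):
        u, _ = mann_whitney_u([1, 2, 2], [2, 3], "two")
        # pairs: (1,*)->0; (2,2)->0.5 twice; (2,3)->0 => U = 1.0
        assert u == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0], "two")


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([0.005, 0.1]), [0.01, 0.1])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_equivalent_to_classical_step_up_rule(self):
        """Rejections via adjusted q-values equal the classical BH rule on
        1,000 random p-vectors."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m)
            alpha = rng.choice([0.01, 0.05, 0.1, 0.25])
            q = bh_fdr(p)
            # classical step-up: find largest i with p_(i) <= i*alpha/m
            order = np.argsort(p)
            ps = p[order]
            thresh = alpha * np.arange(1, m + 1) / m
            below = np.nonzero(ps <= thresh)[0]
            rej_classical = np.zeros(m, bool)
            if below.size:
                rej_classical[order[: below[-1] + 1]] = True
            np.testing.assert_array_equal(q <= alpha, rej_classical)


class TestFisherCombined:
    def test_all_ones(self):
        assert fisher_combined([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        assert fisher_combined([0.2]) == pytest.approx(0.2)

    def test_chi_square_survival_evaluation(self):
        assert fisher_combined([0.05, 0.05]) == pytest.approx(0.01748, abs=2e-5)
        # independent oracle: chi-square survival of -2*sum(log p) with 4 df
        expected = chi2.sf(-2 * (math.log(0.03) + math.log(0.04)), 4)
        assert expected == pytest.approx(0.00926, abs=2e-5)
        assert fisher_combined([0.03, 0.04]) == pytest.approx(expected)

    def test_zero_p_errors(self):
        with pytest.raises(ValueError, match="clip"):
            fisher_combined([0.0, 0.5])


def _two_exp_table(exp1_by_group, exp2_by_group, feature="f1"):
    """Build a 1-feature CountTable + metadata from per-experiment group values."""
    cols, vals, meta_rows = [], [], []
    for exp, by_group in ((1, exp1_by_group), (2, exp2_by_group)):
        for grp, xs in by_group.items():
            for i, v in enumerate(xs):
                sid = f"E{exp}.{grp}.{i}"
                cols.append(sid)
                vals.append(v)
                meta_rows.append((sid, exp, grp))
    table = CountTable(pd.DataFrame([vals], index=[feature], columns=cols))
    meta = SampleMetadata(
        pd.DataFrame(
            {"experiment": [r[1] for r in meta_rows], "group": [r[2] for r in meta_rows]},
            index=pd.Index([r[0] for r in meta_rows], name="sample_id"),
        )
    )
    return table, meta


class TestConsistencyGate:
    def test_opposite_directions_never_significant(self):
        # strongly up in treated in exp1, strongly down in exp2
        table, meta = _two_exp_table(
            {"WD": [1, 2, 3], "WD_Ch": [10, 11, 12]},
            {"WD": [10, 11, 12], "WD_Ch": [1, 2, 3]},
        )
        out = run_consistency_test(table, meta, ("WD_Ch", "WD"), tail="two", fdr_level=0.99)
        rec = out.loc["f1"]
        assert not rec["consistent"]
        assert not rec["significant"]
        assert np.isnan(rec["p"])

    def test_consistent_feature_is_tested(self):
        table, meta = _two_exp_table(
            {"WD": [1, 2, 3, 4, 5], "WD_Ch": [10, 11, 12, 13, 14]},
            {"WD": [2, 3, 4, 5, 6], "WD_Ch": [11, 12, 13, 14, 15]},
        )
        out = run_consistency_test(table, meta, ("WD_Ch", "WD"), tail="two", fdr_level=0.1)
        rec = out.loc["f1"]
        assert rec["consistent"] and rec["direction"] == 1
        assert rec["significant"]

    def test_missing_group_errors(self):
        table, meta = _two_exp_table({"WD": [1, 2]}, {"WD": [1, 2]})
        with pytest.raises(ValueError, match="WD_Ch"):
            run_consistency_test(table, meta, ("WD_Ch", "WD"))


def _stats_frame(sig, direction, consistent=True):
    return pd.DataFrame(
        {
            "consistent": [consistent],
            "direction": [direction],
            "p": [0.01 if sig else 0.5],
        },
        index=["f1"],
    )


class TestClassifyResponseGroups:
    def test_reversed_rule(self):
        labels = classify_response_groups(
            _stats_frame(True, 1),  # up in WD vs ND
            _stats_frame(True, -1),  # down in WD_Ch vs WD
            _stats_frame(False, 0),
            p_threshold=0.1,
        )
        assert labels["f1"] == "reversed"

    def test_treatment_only_rule(self):
        labels = classify_response_groups(
            _stats_frame(False, 0),
            _stats_frame(True, 1),
            _stats_frame(True, 1),
            p_threshold=0.1,
        )
        assert labels["f1"] == "treatment_only"

    def test_diet_only_rule(self):
        labels = classify_response_groups(
            _stats_frame(True, 1),
            _stats_frame(False, 0),
            _stats_frame(True, 1),
            p_threshold=0.1,
        )
        assert labels["f1"] == "diet_only"

    def test_inconsistent_feature_is_none(self):
        labels = classify_response_groups(
            _stats_frame(True, 1, consistent=False),
            _stats_frame(True, -1),
            _stats_frame(False, 0),
            p_threshold=0.1,
        )
        assert labels["f1"] == "none"

    def test_scaling_invariance_before_relativization(self, default_study):
        """Multiplying any sample's raw counts by a positive constant does not
        change response-group labels (per-sample relativization removes it)."""
        from tknet.preprocess import relativize_and_mean_normalize
        from tknet.differential import COMPARISONS

        study = default_study
        raw = pd.concat([study.counts[e].data for e in sorted(study.counts)], axis=1)
        scaled = raw.copy()
        rng = np.random.default_rng(1)
        factors = rng.uniform(0.2, 5.0, size=scaled.shape[1])
        scaled = scaled * factors[None, :]

        def labels_for(frame):
            mean_norm = relativize_and_mean_normalize(CountTable(frame))
            stats = {
                name: comparison_stats(mean_norm.data, study.metadata, comp, tail="two")
                for name, comp in COMPARISONS.items()
            }
            return classify_response_groups(
                stats["WDvsND"], stats["ChvsWD"], stats["ChvsND"], p_threshold=0.05
            )

        pd.testing.assert_series_equal(labels_for(raw), labels_for(scaled))


class TestFamilyDifferential:
    def _family_tables(self):
        rng = np.random.default_rng(8)
        cols1 = [f"E1.{g}.{i}" for g in ("ND", "WD", "WD_Ch") for i in range(5)]
        cols2 = [f"E2.{g}.{i}" for g in ("ND", "WD", "WD_Ch") for i in range(5)]
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "experiment": [1] * 15 + [2] * 15,
                    "group": ([g for g in ("ND", "WD", "WD_Ch") for _ in range(5)]) * 2,
                },
                index=pd.Index(cols1 + cols2, name="sample_id"),
            )
        )
        d1 = pd.DataFrame(rng.random((2, 15)) + 0.1, index=["famA", "famB"], columns=cols1)
        d2 = pd.DataFrame(rng.random((2, 15)) + 0.1, index=["famA", "famC"], columns=cols2)
        # famA strongly elevated in WD in both experiments
        d1.loc["famA", [c for c in cols1 if ".WD." in c]] += 5
        d2.loc["famA", [c for c in cols2 if ".WD." in c]] += 5
        return {1: CountTable(d1), 2: CountTable(d2)}, meta

    def test_consistent_family_combined_and_mismatch_skipped(self):
        tables, meta = self._family_tables()
        with pytest.warns(UserWarning, match="skipping"):
            out = family_differential(tables, meta, ("WD", "ND"))
        assert list(out.index) == ["famA"]  # famB/famC absent from one experiment
        rec = out.loc["famA"]
        assert rec["consistent"]
        # Fisher's method on the per-experiment p-values
        expected = chi2.sf(-2 * (math.log(rec["p_exp1"]) + math.log(rec["p_exp2"])), 4)
        assert rec["combined_p"] == pytest.approx(expected)
        assert rec["significant"]

    def test_inconsistent_direction_excluded(self):
        tables, meta = self._family_tables()
        # flip experiment 2's famA direction
        d2 = tables[2].data.copy()
        wd = [c for c in d2.columns if ".WD." in c]
        d2.loc["famA", wd] -= 10
        d2 = d2.clip(lower=0.01)
        tables = {1: tables[1], 2: CountTable(d2)}
        with pytest.warns(UserWarning):
            out = family_differential(tables, meta, ("WD", "ND"))
        assert not out.loc["famA", "consistent"]
        assert np.isnan(out.loc["famA", "combined_p"])
        assert not out.loc["famA", "significant"]

    def test_null_pvalues_combine_to_one(self):
        assert fisher_combined([1.0, 1.0]) == pytest.approx(1.0)
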
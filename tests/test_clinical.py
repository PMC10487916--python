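import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from mircna.clinical import (
    CtRecord,
    associate,
    combine_scores,
    km_logrank,
    median_split,
    multivariate_association,
    relative_quantity,
    roc_auc,
)
from mircna import synthetic

from oracles import auc_pair_count, logrank_tabulation, welch_t_p


def ct(sample="S1", tissue="tumor", target=(28.0, 28.0, 28.0), ref=(25.0, 25.0, 25.0)):
    return CtRecord(sample, tissue, "miR-X", target, ref)


class TestRelativeQuantity:
    def test_calibrator_identity(self):
        res = relative_quantity(ct(target=(26.0, 26.0, 26.0)), calibrator_delta_ct=1.0)
        assert not res.excluded
        assert res.rq == pytest.approx(1.0)

    def test_reference_at_31_excluded(self):
        res = relative_quantity(ct(ref=(31.0, 31.0, 31.0)), calibrator_delta_ct=0.0)
        assert res.excluded
        assert "reference" in res.reason

    def test_target_at_35_excluded(self):
        res = relative_quantity(ct(target=(35.0, 35.0, 35.0)), calibrator_delta_ct=0.0)
        assert res.excluded

    def test_direct_formula(self):
        # dCt = 28 - 25 = 3, ddCt = 3 - 1 = 2, RQ = 2^-2
        res = relative_quantity(ct(), calibrator_delta_ct=1.0)
        assert res.delta_ct == pytest.approx(3.0)
        assert res.rq == pytest.approx(0.25)

    def test_replicates_averaged(self):
        res = relative_quantity(
            ct(target=(27.0, 28.0, 29.0), ref=(24.0, 25.0, 26.0)), calibrator_delta_ct=0.0
        )
        assert res.delta_ct == pytest.approx(3.0)

    def test_missing_replicate_names_sample(self):
        with pytest.raises(ValueError, match="S9"):
            CtRecord("S9", "tumor", "miR-X", (28.0, np.nan, 28.0), (25.0, 25.0, 25.0))

    def test_monotone_in_target_and_reference_ct(self):
        low = relative_quantity(ct(target=(27.0,) * 3), 0.0).rq
        high = relative_quantity(ct(target=(29.0,) * 3), 0.0).rq
        assert low > high  # more target -> lower Ct -> higher RQ
        ref_lo = relative_quantity(ct(ref=(24.0,) * 3), 0.0).rq
        ref_hi = relative_quantity(ct(ref=(26.0,) * 3), 0.0).rq
        assert ref_hi > ref_lo


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], ["ANT"] * 3 + ["tumor"] * 3, n_bootstrap=50)
        assert res.auc == 1.0

    def test_identical_scores_give_half(self):
        res = roc_auc([5] * 6, ["ANT", "tumor"] * 3, n_bootstrap=50)
        assert res.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=20), 1)  # rounding forces some ties
        labels = ["tumor" if rng.random() < 0.5 else "ANT" for _ in range(20)]
        if len(set(labels)) < 2:
            labels[0] = "tumor" if labels[1] == "ANT" else "ANT"
        res = roc_auc(scores, labels, n_bootstrap=10)
        assert res.auc == pytest.approx(auc_pair_count(scores, labels))

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = ["tumor"] * 15 + ["ANT"] * 15
        a = roc_auc(scores, labels, n_bootstrap=10).auc
        b = roc_auc(-scores, labels, n_bootstrap=10).auc
        assert a + b == pytest.approx(1.0)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)])
        labels = ["ANT"] * 15 + ["tumor"] * 15
        res = roc_auc(scores, labels, n_bootstrap=500, seed=1)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0 < res.ci_low < res.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], ["tumor", "tumor"])


class TestCombineScores:
    def test_identical_features_equal_single_z(self):
        x = np.array([1.0, 3.0, 5.0, 7.0])
        df = pd.DataFrame([x, x, x], index=list("abc"), columns=list("wxyz"))
        combined = combine_scores(df)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(combined.to_numpy(), z)

    def test_mirrored_features_cancel(self):
        x = np.array([1.0, 3.0, 5.0, 7.0])
        df = pd.DataFrame([x, -x], index=list("ab"), columns=list("wxyz"))
        np.testing.assert_allclose(combine_scores(df).to_numpy(), 0.0, atol=1e-12)

    def test_combined_auc_equals_recomputation(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            rng.normal(size=(4, 24)), index=list("abcd"),
            columns=[f"S{i}" for i in range(24)],
        )
        labels = ["tumor"] * 12 + ["ANT"] * 12
        combined = combine_scores(df)
        z = (df.to_numpy() - df.to_numpy().mean(axis=1, keepdims=True)) / df.to_numpy().std(
            axis=1, ddof=1, keepdims=True
        )
        manual = z.mean(axis=0)
        assert roc_auc(combined, labels, n_bootstrap=10).auc == pytest.approx(
            roc_auc(manual, labels, n_bootstrap=10).auc
        )

    def test_zero_variance_feature_rejected(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            combine_scores(df)


def clinical_frame(n, seed=0, **overrides):
    table, _ = synthetic.generate_clinical(
        n, np.zeros(n), hazard_coef=0.0, baseline_hazard=0.02,
        censor_month=60.0, seed=seed,
    )
    for k, v in overrides.items():
        table[k] = v
    return table


class TestAssociate:
    def test_separated_strata_highly_significant(self):
        table = clinical_frame(20, tumor_size=[1.0] * 10 + [3.0] * 10)
        expr = pd.Series(
            np.concatenate([np.random.default_rng(1).normal(0, 0.1, 10),
                            np.random.default_rng(2).normal(5, 0.1, 10)]),
            index=table["patient_id"],
        )
        res = associate(expr, table, "tumor_size")
        assert res.p_value < 1e-3
        assert res.cutpoint == 1.7

    def test_welch_formula_oracle(self):
        table = clinical_frame(12, age=[40.0] * 6 + [70.0] * 6)
        values = np.array([1.2, 0.8, 1.5, 0.9, 1.1, 1.3, 2.5, 2.2, 2.8, 2.4, 2.0, 2.6])
        expr = pd.Series(values, index=table["patient_id"])
        res = associate(expr, table, "age")
        _, p_expected = welch_t_p(values[6:], values[:6])  # high = age > 55.5
        assert res.p_value == pytest.approx(p_expected)
        assert res.mean_high == pytest.approx(values[6:].mean())

    def test_binary_variable_uses_levels(self):
        table = clinical_frame(10, recurrence=[False] * 5 + [True] * 5)
        expr = pd.Series(np.arange(10.0), index=table["patient_id"])
        res = associate(expr, table, "recurrence")
        assert res.cutpoint is None
        assert res.mean_high == pytest.approx(7.0)  # True stratum

    def test_tiny_stratum_rejected(self):
        table = clinical_frame(6, age=[80.0] + [40.0] * 5)
        expr = pd.Series(np.arange(6.0), index=table["patient_id"])
        with pytest.raises(ValueError, match="stratum"):
            associate(expr, table, "age")


class TestMultivariate:
    def test_single_binary_covariate_matches_pooled_t(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.5, 20)
        table = multivariate_association(
            pd.Series(y), pd.DataFrame({"flag": x.astype(bool)})
        )
        _, p_t = stats.ttest_ind(y[x == 1], y[x == 0], equal_var=True)
        assert table.loc["flag", "p_value"] == pytest.approx(p_t)

    def test_recovers_known_coefficient(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = 2.0 * x + rng.normal(0, 0.01, 50)
        fit = multivariate_association(pd.Series(y), pd.DataFrame({"x": x}))
        assert abs(fit.loc["x", "coef"] - 2.0) < 3 * fit.loc["x", "stderr"]

    def test_orthogonal_covariates_stable_coefficients(self):
        rng = np.random.default_rng(12)
        n = 40
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)  # orthogonal to a by construction
        y = 3 * a + rng.normal(0, 0.1, n)
        both = multivariate_association(pd.Series(y), pd.DataFrame({"a": a, "b": b}))
        alone = multivariate_association(pd.Series(y), pd.DataFrame({"a": a}))
        assert both.loc["a", "coef"] == pytest.approx(alone.loc["a", "coef"])

    def test_collinear_design_names_columns(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="dup"):
            multivariate_association(
                pd.Series(x), pd.DataFrame({"x": x, "dup": 2 * x})
            )


class TestMedianSplit:
    def test_even_vector(self):
        assert median_split([1, 2, 3, 4]) == ["low", "low", "high", "high"]

    def test_all_equal_warns_and_goes_low(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = median_split([5, 5, 5])
        assert labels == ["low", "low", "low"]

    def test_odd_count_splits_fifty_fifty(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=101)
        labels = median_split(values)
        assert labels.count("high") == 50
        assert labels.count("low") == 51


class TestKmLogrank:
    def _frame(self, times, deceased):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(len(times))],
                "follow_up": times,
                "status": ["deceased" if d else "alive" for d in deceased],
            }
        )

    def test_no_events_flat_curves_zero_statistic(self):
        table = self._frame([10, 20, 30, 40], [False] * 4)
        res = km_logrank(table, ["low", "low", "high", "high"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        for curve in res.curves.values():
            assert (curve["survival"] == 1.0).all()

    def test_identical_groups_give_null_statistic(self):
        times = [5, 10, 15, 20, 25, 30]
        dead = [True, True, False, True, False, True]
        table = self._frame(times * 2, dead * 2)
        labels = ["A"] * 6 + ["B"] * 6
        res = km_logrank(table, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_preserves_statistic(self):
        rng = np.random.default_rng(14)
        table = self._frame(rng.exponential(20, 30).round(2), rng.random(30) < 0.6)
        labels = ["high" if v else "low" for v in rng.random(30) < 0.5]
        swapped = ["low" if l == "high" else "high" for l in labels]
        a = km_logrank(table, labels)
        b = km_logrank(table, swapped)
        assert a.statistic == pytest.approx(b.statistic)

    def test_event_tables_match_hand_tabulation(self):
        # 12-record fixture with ties and censoring
        times = [3, 5, 5, 7, 8, 8, 10, 12, 12, 15, 18, 20]
        dead = [True, True, False, True, True, True, False, True, False, True, False, False]
        group1 = [True, False, True, True, False, True, False, True, False, False, True, False]
        table = self._frame(times, dead)
        labels = ["g1" if g else "g2" for g in group1]
        res = km_logrank(table, labels)
        rows, stat, _ = logrank_tabulation(times, dead, group1)
        got = res.event_table
        assert len(got) == len(rows)
        for (t, n, n1, d, d1, e1), (_, row) in zip(rows, got.iterrows()):
            assert row["time"] == t
            assert row["at_risk"] == n
            assert row["at_risk_g1"] == n1
            assert row["events"] == d
            assert row["observed_g1"] == d1
            assert row["expected_g1"] == pytest.approx(e1)
        assert res.statistic == pytest.approx(stat)

    def test_statistic_matches_lifelines(self):
        rng = np.random.default_rng(15)
        times = rng.exponential(20, 40).round(1)
        dead = rng.random(40) < 0.7
        group = rng.random(40) < 0.5
        table = self._frame(times, dead)
        res = km_logrank(table, ["A" if g else "B" for g in group])
        lr = logrank_test(times[group], times[~group], dead[group], dead[~group])
        assert res.statistic == pytest.approx(lr.test_statistic)
        assert res.p_value == pytest.approx(lr.p_value)

    def test_all_censored_at_zero_rejected(self):
        table = self._frame([0, 0], [False, False])
        with pytest.raises(ValueError, match="time 0"):
            km_logrank(table, ["A", "B"])
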
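"""Estimator identities against closed-form oracles, and the Wald tests."""

import numpy as np
import pandas as pd
import pytest

from listcount import (
    LongDataset,
    burkina_config,
    estimate_pooled,
    estimate_single_list,
    estimate_subgroup,
    simulate_survey,
    to_long,
    wald_equal_lists,
    wald_vs_direct,
)
from listcount.estimation import DegenerateDesignError
from listcount.summaries import (
    misreport_gap,
    pooled_prevalence_balanced,
    prevalence_from_arm_means,
    wald_equal_summary,
    wald_vs_direct_summary,
)

from conftest import make_long


class TestSingleList:
    def test_hand_computed_difference_of_means(self):
        est = estimate_single_list(LongDataset(make_long([1, 2], [2, 3])))
        assert est.beta == pytest.approx(1.0)
        assert est.lam == pytest.approx(1.5)

    def test_identical_arms_give_zero(self):
        est = estimate_single_list(LongDataset(make_long([0, 1, 2, 3], [0, 1, 2, 3])))
        assert est.beta == pytest.approx(0.0, abs=1e-12)

    def test_ols_equals_cell_means_to_machine_precision(self):
        rng = np.random.default_rng(42)
        y0 = rng.integers(0, 4, size=200)
        y1 = rng.integers(0, 5, size=180)
        est = estimate_single_list(LongDataset(make_long(list(y0), list(y1))))
        assert est.beta == pytest.approx(y1.mean() - y0.mean(), abs=1e-12)
        assert est.lam == pytest.approx(y0.mean(), abs=1e-12)
        assert est.arm_means == (pytest.approx(y1.mean()), pytest.approx(y0.mean()))

    def test_classical_se_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(7)
        y0, y1 = rng.integers(0, 4, 50), rng.integers(0, 5, 60)
        est = estimate_single_list(LongDataset(make_long(list(y0), list(y1))), se_flavor="classical")
        resid = np.concatenate([y0 - y0.mean(), y1 - y1.mean()])
        s2 = resid @ resid / (110 - 2)
        assert est.se == pytest.approx(np.sqrt(s2 * (1 / 50 + 1 / 60)), rel=1e-10)

    def test_single_arm_is_degenerate(self):
        df = make_long([1, 2, 3], [])
        with pytest.raises(DegenerateDesignError):
            estimate_single_list(LongDataset(df))

    def test_ci_is_beta_plus_minus_1p96_se(self):
        est = estimate_single_list(LongDataset(make_long([1, 2, 0], [2, 3, 1])))
        assert est.ci95[0] == pytest.approx(est.beta - 1.96 * est.se)
        assert est.ci95[1] == pytest.approx(est.beta + 1.96 * est.se)


class TestPooled:
    def test_identical_lists_reduce_to_single_beta(self):
        a = make_long([1, 2, 0], [2, 3, 1], "A")
        b = make_long([1, 2, 0], [2, 3, 1], "B")
        b["respondent_id"] = b["respondent_id"] + 10
        pooled = estimate_pooled(LongDataset(pd.concat([a, b], ignore_index=True)))
        single = estimate_single_list(LongDataset(a))
        assert pooled.beta == pytest.approx(single.beta, abs=1e-10)

    def test_six_respondent_fixture_matches_normal_equations(self):
        rows = []
        y_a = [3, 2, 4, 1, 2, 3]
        y_b = [2, 3, 1, 3, 2, 2]
        for i in range(6):
            group = 1 if (i + 1) % 2 == 1 else 2
            rows.append({"respondent_id": i, "list": "A", "Y": y_a[i], "T": int(group == 1), "list_A_flag": 1})
            rows.append({"respondent_id": i, "list": "B", "Y": y_b[i], "T": int(group == 2), "list_A_flag": 0})
        long = LongDataset(pd.DataFrame(rows))
        est = estimate_pooled(long)
        # brute-force 3x3 least squares
        df = long.df
        x = np.column_stack([np.ones(12), df["T"], df["list_A_flag"]])
        coef = np.linalg.solve(x.T @ x, x.T @ df["Y"].to_numpy(dtype=float))
        assert est.lam == pytest.approx(coef[0], abs=1e-10)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)

    def test_balanced_design_identity(self, burkina_long):
        est_a = estimate_single_list(burkina_long.restrict("A"))
        est_b = estimate_single_list(burkina_long.restrict("B"))
        pooled = estimate_pooled(burkina_long)
        assert pooled.beta == pytest.approx(0.5 * (est_a.beta + est_b.beta), abs=1e-10)
        assert pooled.clustered and pooled.se_flavor == "cluster-robust"

    def test_cluster_covariance_is_symmetric_psd(self, burkina_long):
        import statsmodels.api as sm

        df = burkina_long.df
        x = sm.add_constant(np.column_stack([df["T"], df["list_A_flag"]]))
        fit = sm.OLS(df["Y"].astype(float), x).fit(
            cov_type="cluster", cov_kwds={"groups": df["respondent_id"], "use_correction": True}
        )
        cov = np.asarray(fit.cov_params())
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-12


class TestSubgroup:
    @staticmethod
    def _fixture():
        # cell means: S=0 control 1.0 treated 1.5; S=1 control 1.0 treated 2.0
        rows = []
        data = [
            (0, 0, [1, 1]), (0, 1, [1, 2]),  # S=0: control mean 1, treated mean 1.5
            (1, 0, [1, 1]), (1, 1, [2, 2]),  # S=1: control mean 1, treated mean 2
        ]
        rid = 0
        for s, t, ys in data:
            for y in ys:
                rows.append({"respondent_id": rid, "list": "A", "Y": y, "T": t, "list_A_flag": 1, "S": s})
                rid += 1
        return LongDataset(pd.DataFrame(rows))

    def test_saturated_cell_mean_identity(self):
        est = estimate_subgroup(self._fixture(), "S")
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.alpha == pytest.approx(0.5, abs=1e-10)
        assert est.prevalence_s1 == pytest.approx(est.beta + est.alpha)

    def test_empty_cell_raises(self):
        long = self._fixture()
        df = long.df[~((long.df["S"] == 1) & (long.df["T"] == 1))]
        with pytest.raises(DegenerateDesignError, match="empty"):
            estimate_subgroup(LongDataset(df.copy()), "S")

    def test_independent_subgroup_has_null_interaction(self):
        from listcount import with_subgroup

        config = with_subgroup(burkina_config(seed=55, n=20000), "flag", prob=0.5, shift=0.0)
        long = to_long(simulate_survey(config))
        est = estimate_subgroup(long.restrict("A"), "flag")
        assert abs(est.alpha) < 3 * np.hypot(est.se_beta, est.se_prevalence_s1)


class TestWaldEqualLists:
    def test_identical_lists_give_zero_difference_p_one(self):
        a = make_long([1, 2, 0], [2, 3, 1], "A")
        b = a.copy()
        b["list"] = "B"
        b["list_A_flag"] = 0
        b["T"] = a["T"].to_numpy()  # same respondents, same roles
        long = LongDataset(pd.concat([a, b], ignore_index=True))
        res = wald_equal_lists(long)
        assert res.difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_summary_difference_matches_printed_estimates(self):
        res = wald_equal_summary(0.800, 0.062, 0.793, 0.058)
        assert res.difference == pytest.approx(-0.007, abs=1e-12)
        assert res.p_value > 0.9

    def test_null_rejection_rate_is_nominal(self):
        """Stacked-clustered test size: ~5% rejections when both lists share
        the same prevalence."""
        rejections = 0
        n_reps = 400
        for seed in range(n_reps):
            long = to_long(simulate_survey(burkina_config(seed=700_000 + seed, n=400)))
            if wald_equal_lists(long).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_single_list_unsupported(self):
        with pytest.raises(ValueError):
            wald_equal_lists(LongDataset(make_long([1, 2], [2, 3])))


class TestWaldVsDirect:
    def test_printed_inputs_reproduce_p_values(self):
        res = wald_vs_direct_summary(0.800, 0.062, 0.968, 495)
        assert round(res.p_value, 3) == 0.007
        res_b = wald_vs_direct_summary(0.793, 0.058, 0.968, 495)
        assert round(res_b.p_value, 3) == 0.003

    def test_equal_estimates_give_p_one(self):
        res = wald_vs_direct_summary(0.5, 0.04, 0.5, 100)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_dataset_route_matches_summary_route(self, burkina_cohort, burkina_long):
        est = estimate_single_list(burkina_long.restrict("A"))
        direct = burkina_cohort.df["direct_report"]
        via_data = wald_vs_direct(est, burkina_cohort)
        via_summary = wald_vs_direct_summary(est.beta, est.se, direct.mean(), len(direct))
        assert via_data.p_value == pytest.approx(via_summary.p_value, rel=1e-12)

    def test_stacked_variant_accounts_for_shared_respondents(self, burkina_cohort, burkina_long):
        est = estimate_single_list(burkina_long.restrict("A"))
        res = wald_vs_direct(est, burkina_cohort, method="stacked")
        assert res.method == "stacked"
        assert res.se_diff > 0


class TestSummaries:
    def test_arm_mean_arithmetic(self):
        assert prevalence_from_arm_means(2.43, 1.63) == pytest.approx(0.800)
        assert misreport_gap(0.968, 0.800) == pytest.approx(0.168)
        assert pooled_prevalence_balanced(0.215, 0.261) == pytest.approx(0.238)
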
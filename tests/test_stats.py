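import numpy as np
import pandas as pd
import pytest

from tractofit.cohort import (MetricEffect, EffectSpec, default_effect_spec,
                              simulate_cohort)
from tractofit.errors import (InsufficientSampleError, ParameterError,
                              SingularDesignError)
from tractofit.stats import (BatteryConfig, analysis_battery,
                             ancova_group_test, bonferroni_threshold,
                             display_threshold, partial_correlation,
                             stepwise_blocks)


def fixed_table():
    """A small deterministic cohort table for closed-form checks."""
    rng = np.random.default_rng(42)
    n = 12
    return pd.DataFrame({
        "group": ["HC"] * 6 + ["PMS"] * 6,
        "age": np.linspace(35, 68, n),
        "sex": ["F", "M"] * 6,
        "metric": rng.normal(10, 2, n),
        "x": rng.normal(0, 1, n),
        "y": rng.normal(0, 1, n),
        "z1": rng.normal(0, 1, n),
        "z2": rng.normal(0, 1, n),
    })


class TestAncova:
    def test_matches_normal_equations_oracle(self):
        cohort = fixed_table()
        res = ancova_group_test(cohort, "metric")
        X = np.column_stack([
            np.ones(12),
            (cohort["group"] == "PMS").astype(float),
            cohort["age"],
            (cohort["sex"] == "M").astype(float),
        ])
        y = cohort["metric"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert abs(res.estimate - beta[1]) < 1e-10
        resid = y - X @ beta
        sigma2 = resid @ resid / (12 - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(res.se - se) < 1e-10

    def test_group_t_equals_one_df_f(self):
        cohort = fixed_table()
        res = ancova_group_test(cohort, "metric")
        # t^2 == F for the 1-df group contrast
        import statsmodels.api as sm
        X = np.column_stack([
            np.ones(12), (cohort["group"] == "PMS").astype(float),
            cohort["age"], (cohort["sex"] == "M").astype(float)])
        full = sm.OLS(cohort["metric"], X).fit()
        reduced = sm.OLS(cohort["metric"], X[:, [0, 2, 3]]).fit()
        F = ((reduced.ssr - full.ssr) / 1) / (full.ssr / full.df_resid)
        assert np.isclose(res.statistic**2, F)

    def test_zero_variance_metric_flagged(self):
        cohort = fixed_table()
        cohort["metric"] = 5.0
        res = ancova_group_test(cohort, "metric")
        assert res.p == 1.0 and res.estimate == 0.0
        assert res.detail["zero_variance"]

    def test_collinear_covariates_rejected(self):
        cohort = fixed_table()
        cohort["age2"] = cohort["age"] * 2
        with pytest.raises(SingularDesignError):
            ancova_group_test(cohort, "metric", ("age", "age2"))

    def test_p_invariant_to_covariate_rescaling(self):
        cohort = fixed_table()
        a = ancova_group_test(cohort, "metric", ("age",))
        cohort2 = cohort.copy()
        cohort2["age"] = cohort2["age"] * 12 + 3
        b = ancova_group_test(cohort2, "metric", ("age",))
        assert np.isclose(a.p, b.p)

    def test_type_one_error_calibrated(self):
        """Group-term rejection rate under the null stays near alpha."""
        spec = default_effect_spec(density_shift=0, direct_shift=0)
        rej = 0
        reps = 400
        for r in range(reps):
            cohort = simulate_cohort(24, 42, spec, seed=r)
            rej += ancova_group_test(cohort, "mean_strength").p < 0.05
        assert abs(rej / reps - 0.05) < 0.025


class TestPartialCorrelation:
    def test_empty_covariates_is_plain_pearson(self):
        cohort = fixed_table()
        res = partial_correlation(cohort, "x", "y", ())
        expected = np.corrcoef(cohort["x"], cohort["y"])[0, 1]
        assert abs(res.r - expected) < 1e-12

    def test_perfect_correlation(self):
        cohort = fixed_table()
        cohort["y"] = cohort["x"]
        res = partial_correlation(cohort, "x", "y", ())
        assert np.isclose(res.r, 1.0)
        assert res.p == 0.0

    def test_matches_recursive_formula_oracle(self):
        """r_xy.z1z2 by the textbook recursion on a fixed 10-row table."""
        rng = np.random.default_rng(7)
        cohort = pd.DataFrame(rng.normal(size=(10, 4)),
                              columns=["x", "y", "z1", "z2"])

        def r(a, b):
            return np.corrcoef(cohort[a], cohort[b])[0, 1]

        def partial1(ab, az, bz):  # r_ab.z
            return (ab - az * bz) / np.sqrt((1 - az**2) * (1 - bz**2))

        # recurse: condition on z1 first, then z2
        rxy_1 = partial1(r("x", "y"), r("x", "z1"), r("y", "z1"))
        rx2_1 = partial1(r("x", "z2"), r("x", "z1"), r("z2", "z1"))
        ry2_1 = partial1(r("y", "z2"), r("y", "z1"), r("z2", "z1"))
        expected = partial1(rxy_1, rx2_1, ry2_1)
        res = partial_correlation(cohort, "x", "y", ("z1", "z2"))
        assert abs(res.r - expected) < 1e-12

    def test_symmetry_in_x_and_y(self):
        cohort = fixed_table()
        a = partial_correlation(cohort, "x", "y", ("age",))
        b = partial_correlation(cohort, "y", "x", ("age",))
        assert np.isclose(a.r, b.r) and np.isclose(a.p, b.p)

    def test_insufficient_sample_rejected(self):
        cohort = fixed_table().head(4)
        with pytest.raises(ParameterError):
            partial_correlation(cohort, "x", "y", ("age", "z1"))


class TestStepwise:
    def test_perfect_predictor_selected_with_r2_one(self):
        cohort = fixed_table()
        cohort["outcome"] = 3.0 * cohort["x"] - 1.0
        res = stepwise_blocks(cohort, "outcome", ("age", "sex"),
                              ("x", "z1", "z2"))
        assert res.detail["selected"][0] == "x"
        assert res.r2 > 1 - 1e-10

    def test_strong_single_candidate_matches_full_ols(self):
        rng = np.random.default_rng(3)
        n = 40
        cohort = pd.DataFrame({
            "group": ["HC"] * 20 + ["PMS"] * 20,
            "age": rng.normal(50, 8, n),
            "sex": rng.choice(["F", "M"], n),
            "x": rng.normal(0, 1, n),
        })
        cohort["outcome"] = 2.0 * cohort["x"] + rng.normal(0, 0.5, n)
        res = stepwise_blocks(cohort, "outcome", ("age", "sex"), ("x",))
        assert res.detail["selected"] == ["x"]
        import statsmodels.api as sm
        X = np.column_stack([np.ones(n), cohort["age"],
                             (cohort["sex"] == "M").astype(float),
                             cohort["x"]])
        full = sm.OLS(cohort["outcome"], X).fit()
        assert np.isclose(res.r2, full.rsquared)

    def test_null_candidates_selected_at_entry_rate(self):
        """Independent null candidates enter roughly at p_enter."""
        rng = np.random.default_rng(0)
        n = 60
        count = 0
        reps = 300
        for _ in range(reps):
            cohort = pd.DataFrame({
                "age": rng.normal(50, 8, n),
                "sex": rng.choice(["F", "M"], n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
                "outcome": rng.normal(size=n),
            })
            res = stepwise_blocks(cohort, "outcome", ("age", "sex"),
                                  ("c1", "c2"))
            count += "c1" in res.detail["selected"]
        rate = count / reps
        assert abs(rate - 0.05) < 0.035

    def test_no_candidate_passing_entry_keeps_block1_only(self):
        cohort = fixed_table()
        cohort["outcome"] = cohort["age"] * 2.0  # block-1 explains all
        res = stepwise_blocks(cohort, "outcome", ("age", "sex"),
                              ("z1",), p_enter=1e-6)
        assert res.detail["selected"] == []
        assert res.detail["block1_only"]

    def test_invalid_criteria_rejected(self):
        cohort = fixed_table()
        with pytest.raises(ParameterError):
            stepwise_blocks(cohort, "metric", ("age",), ("x",),
                            p_enter=0.2, p_remove=0.1)
        with pytest.raises(ParameterError):
            stepwise_blocks(cohort, "metric", ("age",), ())


class TestBonferroni:
    def test_reference_thresholds(self):
        assert np.isclose(bonferroni_threshold(0.05, 6), 0.05 / 6)
        assert display_threshold(0.05, 6) == 0.008
        assert np.isclose(bonferroni_threshold(0.05, 14), 0.05 / 14)
        assert display_threshold(0.05, 14) == 0.004
        assert bonferroni_threshold(0.31, 1) == 0.31

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ParameterError):
            bonferroni_threshold(1.5, 3)

    def test_family_wise_error_controlled_under_null(self):
        """Bonferroni over the six null global metrics keeps the
        family-wise error at or below alpha."""
        spec = default_effect_spec(density_shift=0, direct_shift=0)
        thr = bonferroni_threshold(0.05, 6)
        fw = 0
        reps = 300
        metrics = list(spec.metrics)
        for r in range(reps):
            cohort = simulate_cohort(24, 42, spec, seed=10_000 + r)
            fw += any(ancova_group_test(cohort, m).p < thr for m in metrics)
        assert fw / reps <= 0.05 + 0.03


class TestCohortGenerator:
    def test_deterministic_given_seed(self):
        a = simulate_cohort(10, 12, seed=3)
        b = simulate_cohort(10, 12, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_group_rejected(self):
        with pytest.raises(InsufficientSampleError):
            simulate_cohort(2, 42)

    def test_null_spec_produces_balanced_groups(self):
        spec = default_effect_spec(density_shift=0, direct_shift=0)
        diffs = []
        for seed in range(40):
            c = simulate_cohort(24, 42, spec, seed=seed)
            hc = c[c.group == "HC"]["density"]
            pms = c[c.group == "PMS"]["density"]
            se = np.sqrt(hc.var() / len(hc) + pms.var() / len(pms))
            diffs.append(abs(hc.mean() - pms.mean()) / se)
        # mean standardized difference ~ |N(0,1)| on average (~0.8)
        assert np.mean(diffs) < 1.5

    def test_strong_density_shift_detected_by_t_test(self):
        from scipy import stats as sps
        spec = default_effect_spec(density_shift=-1.5, direct_shift=0)
        hits = 0
        reps = 200
        for seed in range(reps):
            c = simulate_cohort(24, 42, spec, seed=seed)
            t = sps.ttest_ind(c[c.group == "HC"]["density"],
                              c[c.group == "PMS"]["density"])
            hits += t.pvalue < 0.05
        assert hits / reps >= 0.99


class TestBattery:
    def test_density_row_has_no_density_adjusted_p(self):
        cohort = simulate_cohort(24, 42, seed=0)
        table = analysis_battery(cohort)
        row = table[(table.metric == "density") & (table.test == "ancova")]
        assert row["p_b"].isna().all()
        others = table[(table.family == "global") & (table.metric != "density")]
        assert others["p_b"].notna().all()

    def test_mediated_effect_vanishes_with_density_covariate(self):
        spec = default_effect_spec(density_shift=-1.5, direct_shift=0.0,
                                   mediation=0.9)
        hits = 0
        reps = 60
        for seed in range(reps):
            cohort = simulate_cohort(24, 42, spec, seed=seed)
            pa = ancova_group_test(cohort, "global_efficiency").p
            pb = ancova_group_test(cohort, "global_efficiency",
                                   ("age", "sex", "density")).p
            hits += (pa < 0.05) and (pb >= 0.05)
        assert hits / reps >= 0.90

    def test_direct_effect_survives_density_covariate(self):
        spec = default_effect_spec(density_shift=-1.5, direct_shift=-1.5,
                                   mediation=0.0)
        hits = 0
        reps = 60
        for seed in range(reps):
            cohort = simulate_cohort(24, 42, spec, seed=seed)
            pa = ancova_group_test(cohort, "global_efficiency").p
            pb = ancova_group_test(cohort, "global_efficiency",
                                   ("age", "sex", "density")).p
            hits += (pa < 0.05) and (pb < 0.05)
        assert hits / reps >= 0.90

    def test_battery_emits_all_families(self):
        cohort = simulate_cohort(24, 42, seed=1)
        table = analysis_battery(cohort, BatteryConfig(
            outcomes=("edss", "nhpt", "t25fw")))
        assert set(table["family"]) == {"global", "correlation", "stepwise"}
        assert len(table[table.family == "global"]) == 6
        assert len(table[table.family == "correlation"]) == 12
        assert len(table[table.family == "stepwise"]) == 3
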
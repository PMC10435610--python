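import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from megplex import (
    CovariateSpec,
    backward_regression,
    bonferroni_threshold,
    change_scores,
    classify_impairment,
    drop_collinear,
    paired_change_test,
    screen_covariates,
)


def reference_backward_elimination(y, x, threshold=0.10):
    """Independent oracle: backward elimination with numpy least squares and
    t-distribution p-values; returns the retained column indices."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    cols = list(range(x.shape[1]))
    while cols:
        design = np.column_stack([np.ones(len(y)), x[:, cols]])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        dof = len(y) - design.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        tvals = beta / np.sqrt(np.diag(cov))
        pvals = 2 * sps.t.sf(np.abs(tvals), dof)
        worst = int(np.argmax(pvals[1:]))
        if pvals[1:][worst] >= threshold:
            cols.pop(worst)
        else:
            break
    return cols


class TestClassifyImpairment:
    def test_below_cutoff_impaired(self):
        assert classify_impairment(-1.6) is True

    def test_boundary_not_impaired(self):
        assert classify_impairment(-1.5) is False

    def test_above_cutoff_not_impaired(self):
        assert classify_impairment(0.3) is False

    def test_missing_propagates(self):
        assert classify_impairment(float("nan")) is None
        assert classify_impairment(None) is None

    def test_vectorized_with_missing(self):
        out = classify_impairment([-2.0, -1.5, np.nan, 1.0])
        assert out.tolist() == [True, False, pd.NA, False]

    def test_infinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            classify_impairment(float("inf"))


class TestChangeScores:
    def make_cohort(self):
        return pd.DataFrame([
            {"subject_id": "a", "timepoint": "T1", "ec_fpn": 0.40,
             "ef_word_fluency": -1.0, "ef_set_shifting": 0.0},
            {"subject_id": "a", "timepoint": "T2", "ec_fpn": 0.45,
             "ef_word_fluency": -1.2, "ef_set_shifting": 0.5},
            {"subject_id": "b", "timepoint": "T1", "ec_fpn": 0.30,
             "ef_word_fluency": 0.0, "ef_set_shifting": 0.0},
            {"subject_id": "c", "timepoint": "T1", "ec_fpn": 0.50,
             "ef_word_fluency": 0.2, "ef_set_shifting": -0.3},
            {"subject_id": "c", "timepoint": "T2", "ec_fpn": 0.55,
             "ef_word_fluency": np.nan, "ef_set_shifting": -0.1},
        ])

    def test_delta_is_t2_minus_t1(self):
        records = {r.subject_id: r for r in change_scores(self.make_cohort())}
        assert records["a"].delta_ec == pytest.approx(0.05)
        assert records["a"].delta_ef["ef_word_fluency"] == pytest.approx(-0.2)

    def test_single_timepoint_subject_omitted(self):
        assert {r.subject_id for r in change_scores(self.make_cohort())} == {
            "a", "c"
        }

    def test_per_test_missingness(self):
        records = {r.subject_id: r for r in change_scores(self.make_cohort())}
        assert "ef_word_fluency" not in records["c"].delta_ef
        assert records["c"].delta_ef["ef_set_shifting"] == pytest.approx(0.2)


class TestPairedChangeTest:
    def test_no_change_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_change_test(x, x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        t1 = rng.standard_normal(30)
        t2 = t1 + 1.0 + 0.1 * rng.standard_normal(30)
        res = paired_change_test(t1, t2)
        assert res.p_value < 0.001
        assert res.n_pairs == 30

    def test_type_i_error_calibration(self):
        rejections = 0
        n_sims = 1000
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            t1 = rng.standard_normal(30)
            t2 = t1 + rng.standard_normal(30)
            if paired_change_test(t1, t2).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(5)
        t1 = rng.standard_normal(40)
        t2 = t1 + rng.exponential(1.0, 40) ** 3
        assert paired_change_test(t1, t2).test_used == "wilcoxon"

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            paired_change_test([1.0, 2.0], [1.5, 2.5])

    def test_nan_pairs_dropped(self):
        t1 = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        t2 = np.array([1.1, 2.1, 3.1, 4.0, np.nan])
        assert paired_change_test(t1, t2).n_pairs == 3


class TestScreenCovariates:
    def make_cohort(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(n)
        x_assoc = y + 0.3 * rng.standard_normal(n)
        # orthogonalized residual: exactly zero sample association with y
        raw = rng.standard_normal(n)
        x_null = raw - (raw @ y) / (y @ y) * y
        group = np.where(rng.random(n) < 0.5, "a", "b")
        return pd.DataFrame({
            "dep": y, "x_assoc": x_assoc, "x_null": x_null, "group": group,
        })

    def test_null_candidate_excluded(self):
        cohort = self.make_cohort()
        res = screen_covariates(
            cohort, "dep", [CovariateSpec("x_null", "continuous")]
        )
        assert len(res) == 1 and not res[0].selected

    def test_associated_candidate_included(self):
        cohort = self.make_cohort()
        res = screen_covariates(
            cohort, "dep", [CovariateSpec("x_assoc", "continuous")]
        )
        assert res[0].selected

    def test_separated_binary_candidate_included(self):
        rng = np.random.default_rng(3)
        group = np.repeat(["lo", "hi"], 25)
        y = rng.standard_normal(50) + np.where(group == "hi", 2.0, 0.0)
        cohort = pd.DataFrame({"dep": y, "grp": group})
        res = screen_covariates(cohort, "dep", [CovariateSpec("grp", "binary")])
        assert res[0].selected

    def test_empty_candidate_list(self):
        assert screen_covariates(self.make_cohort(), "dep", []) == []

    def test_single_level_candidate_skipped_with_warning(self):
        cohort = self.make_cohort()
        cohort["const"] = "only"
        with pytest.warns(UserWarning, match="single observed level"):
            res = screen_covariates(
                cohort, "dep", [CovariateSpec("const", "binary")]
            )
        assert res == []

    def test_categorical_uses_anova_family(self):
        rng = np.random.default_rng(4)
        lev = rng.choice(["p", "q", "r"], 90)
        y = rng.standard_normal(90) + np.where(lev == "p", 1.5, 0.0)
        cohort = pd.DataFrame({"dep": y, "lev": lev})
        res = screen_covariates(cohort, "dep", [CovariateSpec("lev", "categorical")])
        assert res[0].test_used in ("anova", "kruskal-wallis")
        assert res[0].selected


class TestDropCollinear:
    def test_keeps_first_listed(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(60)
        cohort = pd.DataFrame({
            "a": a, "b": a + 0.01 * rng.standard_normal(60),
            "c": rng.standard_normal(60),
        })
        assert drop_collinear(cohort, ["a", "b", "c"]) == ["a", "c"]
        assert drop_collinear(cohort, ["b", "a", "c"]) == ["b", "c"]


class TestBackwardRegression:
    def test_parameter_recovery_and_null_exclusion(self):
        rng = np.random.default_rng(0)
        n = 500
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 0.5 * x1 + 0.5 * rng.standard_normal(n)
        # population standardized beta = 0.5 * sd(x1) / sd(y)
        pop_beta = 0.5 / np.sqrt(0.5**2 + 0.5**2)
        preds = pd.DataFrame({"x1": x1, "x2": x2})
        res = backward_regression(pd.Series(y, name="y"), preds)
        assert [p for p, _ in res.excluded] == ["x2"]
        (name, beta, p), = res.retained
        assert name == "x1" and p < 0.001
        assert beta == pytest.approx(pop_beta, abs=0.1)

    def test_matches_reference_procedure_across_seeds(self):
        agree = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 60
            x = rng.standard_normal((n, 3))
            y = rng.standard_normal(n)
            preds = pd.DataFrame(x, columns=["a", "b", "c"])
            res = backward_regression(pd.Series(y, name="y"), preds)
            mine = sorted(p for p, _, _ in res.retained)
            ref = sorted(preds.columns[i]
                         for i in reference_backward_elimination(y, x))
            agree += mine == ref
        assert agree == n_seeds

    def test_null_retention_rate_matches_reference(self):
        n_seeds = 500
        mine = ref = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            n = 80
            x = rng.standard_normal((n, 3))
            y = rng.standard_normal(n)
            preds = pd.DataFrame(x, columns=["a", "b", "c"])
            res = backward_regression(pd.Series(y, name="y"), preds)
            mine += len(res.retained) > 0
            ref += len(reference_backward_elimination(y, x)) > 0
        assert abs(mine - ref) / n_seeds <= 0.05

    def test_single_strong_predictor_equals_plain_ols(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        y = x + 0.2 * rng.standard_normal(100)
        preds = pd.DataFrame({"x": x})
        res = backward_regression(pd.Series(y, name="y"), preds)
        assert res.excluded == []
        import statsmodels.api as sm
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.retained[0][2] == pytest.approx(float(fit.pvalues[1]))
        assert res.adj_r2 == pytest.approx(float(fit.rsquared_adj))
        assert res.f_stat == pytest.approx(float(fit.fvalue))
        assert res.model_p == pytest.approx(float(fit.f_pvalue))

    def test_standardized_beta_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        y = 0.6 * x + 0.4 * z + 0.5 * rng.standard_normal(200)
        a = backward_regression(
            pd.Series(y, name="y"), pd.DataFrame({"x": x, "z": z})
        )
        b = backward_regression(
            pd.Series(y, name="y"),
            pd.DataFrame({"x": 1000.0 * x + 77.0, "z": z}),
        )
        for (_, beta_a, p_a), (_, beta_b, p_b) in zip(a.retained, b.retained):
            assert beta_a == pytest.approx(beta_b, rel=1e-8)
            assert p_a == pytest.approx(p_b, rel=1e-6)

    def test_categorical_reference_coding_and_stepwise_removal(self):
        rng = np.random.default_rng(3)
        n = 150
        lev = rng.choice(["ctrl", "m1", "m2"], n)
        x = rng.standard_normal(n)
        y = 0.8 * x + np.where(lev == "m2", 1.0, 0.0) + 0.5 * rng.standard_normal(n)
        preds = pd.DataFrame({"x": x, "lev": lev})
        specs = {"lev": CovariateSpec("lev", "categorical", reference="ctrl")}
        res = backward_regression(pd.Series(y, name="y"), preds, specs)
        retained_names = {p for p, _, _ in res.retained}
        assert "x" in retained_names and "lev[m2]" in retained_names
        all_names = retained_names | {p for p, _ in res.excluded}
        assert all_names == {"x", "lev[m1]", "lev[m2]"}

    def test_exact_collinearity_errors_naming_columns(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        preds = pd.DataFrame({"x": x, "double_x": 2 * x})
        with pytest.raises(ValueError, match="double_x"):
            backward_regression(pd.Series(rng.standard_normal(50), name="y"),
                                preds)

    def test_too_small_n_errors(self):
        preds = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 3)),
                             columns=list("abc"))
        with pytest.raises(ValueError, match="too small"):
            backward_regression(pd.Series(np.zeros(4), name="y"), preds)

    def test_elimination_is_monotone_and_terminates(self):
        rng = np.random.default_rng(6)
        n = 100
        x = rng.standard_normal((n, 5))
        y = rng.standard_normal(n)
        preds = pd.DataFrame(x, columns=list("abcde"))
        res = backward_regression(pd.Series(y, name="y"), preds)
        assert len(res.excluded) + len(res.retained) == 5
        assert all(p >= 0.10 for _, p in res.excluded)
        assert all(p < 0.10 for _, _, p in res.retained)


class TestBonferroni:
    def test_paper_threshold(self):
        assert round(bonferroni_threshold(0.05, 3), 4) == 0.0167

    def test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_half(self):
        assert bonferroni_threshold(0.01, 2) == pytest.approx(0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)
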
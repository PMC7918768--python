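import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from muscletex.stats import (
    adjusted_single_feature_regression,
    bonferroni_flags,
    encode_design,
    fit_ols,
    ks_normality,
    stepwise_regression,
    unpaired_ttest,
)
from oracles import normal_equations_ols


def eight_row_table():
    """Fixed small table with a non-trivial design (full rank)."""
    return pd.DataFrame(
        {
            "sex_male": [0, 0, 0, 0, 1, 1, 1, 1],
            "side_right": [0, 1, 0, 1, 0, 1, 0, 1],
            "age": [25.0, 25.0, 35.0, 35.0, 28.0, 28.0, 33.0, 33.0],
            "bmi": [24.0, 24.5, 27.0, 26.5, 29.0, 29.5, 25.0, 25.5],
            "feat": [1.2, 0.8, 2.5, 2.9, 3.1, 3.6, 1.9, 2.2],
            "mvic": [150.0, 155.0, 138.0, 132.0, 228.0, 232.0, 210.0, 205.0],
        }
    )


class TestUnpairedTTest:
    def test_identical_groups(self):
        r = unpaired_ttest(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_matches_pooled_variance_closed_form(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])
        r = unpaired_ttest(a, b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 6
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        p = 2 * sps.t.sf(abs(t), 6)
        assert r.t == pytest.approx(t, abs=1e-12)
        assert r.p == pytest.approx(p, abs=1e-12)
        assert (r.mean_a, r.mean_b) == (2.5, 4.5)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            unpaired_ttest(np.array([1.0]), np.array([1.0, 2.0]))


class TestFitOls:
    def test_matches_normal_equations_oracle(self):
        tbl = eight_row_table()
        predictors = ["sex_male", "side_right", "age", "bmi", "feat"]
        res = fit_ols(tbl, "mvic", predictors)
        X = np.column_stack(
            [np.ones(8)] + [tbl[c].to_numpy(float) for c in predictors]
        )
        oracle = normal_equations_ols(X, tbl["mvic"].to_numpy())
        for i, name in enumerate(["const"] + predictors):
            assert res.params[name] == pytest.approx(oracle["beta"][i], abs=1e-10)
            assert res.bse[name] == pytest.approx(oracle["se"][i], abs=1e-10)
            assert res.pvalues[name] == pytest.approx(oracle["p"][i], abs=1e-10)
        assert res.r2 == pytest.approx(oracle["r2"], abs=1e-10)
        assert res.r2_adj == pytest.approx(oracle["r2_adj"], abs=1e-10)

    def test_r2_adj_identity(self):
        res = fit_ols(eight_row_table(), "mvic", ["sex_male", "age", "bmi"])
        p = res.n_predictors
        expected = 1 - (1 - res.r2) * (res.n - 1) / (res.n - p - 1)
        assert res.r2_adj == pytest.approx(expected, abs=1e-12)
        assert res.r2_adj <= res.r2 <= 1.0

    def test_term_f_equals_t_squared(self):
        import statsmodels.api as sm

        tbl = eight_row_table()
        X = sm.add_constant(tbl[["sex_male", "age", "bmi"]])
        fit = sm.OLS(tbl["mvic"], X).fit()
        f_test = fit.f_test("bmi = 0")
        assert float(f_test.fvalue) == pytest.approx(
            fit.tvalues["bmi"] ** 2, rel=1e-10
        )
        assert float(f_test.pvalue) == pytest.approx(fit.pvalues["bmi"], rel=1e-10)

    def test_rank_deficient_rejected(self):
        tbl = eight_row_table()
        tbl["dup"] = tbl["bmi"]
        with pytest.raises(ValueError):
            fit_ols(tbl, "mvic", ["bmi", "dup"])


class TestAdjustedSingleFeatureRegression:
    def test_noiseless_linear_outcome_perfectly_recovered(self):
        rng = np.random.default_rng(0)
        n = 40
        tbl = pd.DataFrame(
            {
                "sex": rng.choice(["M", "F"], n),
                "side": rng.choice(["left", "right"], n),
                "age": rng.normal(30, 6, n),
                "bmi": rng.normal(27, 2.6, n),
                "feat": rng.normal(0, 1, n),
            }
        )
        tbl["mvic"] = 100.0 + 7.0 * tbl["feat"]
        res = adjusted_single_feature_regression(tbl, "mvic", "feat")
        assert res.params["feat"] == pytest.approx(7.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.pvalues["feat"] < 1e-12

    def test_null_feature_p_uniform(self):
        # with a pure-noise feature the term p-value is U(0,1); KS sanity check
        rng = np.random.default_rng(123)
        n = 100
        pvals = []
        for _ in range(500):
            tbl = pd.DataFrame(
                {
                    "sex_male": rng.integers(0, 2, n).astype(float),
                    "side_right": rng.integers(0, 2, n).astype(float),
                    "age": rng.normal(30, 6, n),
                    "bmi": rng.normal(27, 2.6, n),
                    "feat": rng.normal(0, 1, n),
                }
            )
            tbl["mvic"] = (
                150 + 80 * tbl["sex_male"] + 3 * tbl["bmi"] + rng.normal(0, 15, n)
            )
            pvals.append(
                adjusted_single_feature_regression(tbl, "mvic", "feat").pvalues[
                    "feat"
                ]
            )
        _, ks_p = sps.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_cluster_robust_changes_se_not_coef(self):
        rng = np.random.default_rng(7)
        n = 30
        tbl = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(n // 2), 2),
                "sex_male": np.repeat(rng.integers(0, 2, n // 2), 2).astype(float),
                "side_right": np.tile([0.0, 1.0], n // 2),
                "age": np.repeat(rng.normal(30, 6, n // 2), 2),
                "bmi": np.repeat(rng.normal(27, 2.6, n // 2), 2),
                "feat": rng.normal(0, 1, n),
            }
        )
        tbl["mvic"] = 150 + 50 * tbl["sex_male"] + rng.normal(0, 10, n)
        plain = adjusted_single_feature_regression(tbl, "mvic", "feat")
        robust = adjusted_single_feature_regression(
            tbl, "mvic", "feat", cluster_by="subject_id"
        )
        assert robust.params["feat"] == pytest.approx(plain.params["feat"], rel=1e-12)
        assert robust.bse["feat"] != pytest.approx(plain.bse["feat"], rel=1e-6)


class TestStepwise:
    @staticmethod
    def null_table(rng, n=60, k=10):
        tbl = pd.DataFrame(
            rng.normal(0, 1, (n, k)), columns=[f"x{i}" for i in range(k)]
        )
        tbl["y"] = rng.normal(0, 1, n)
        return tbl

    def test_p_enter_zero_gives_empty_model(self, rng):
        tbl = self.null_table(rng)
        sw = stepwise_regression(tbl, "y", [f"x{i}" for i in range(10)], p_enter=0.0)
        assert sw.selected == [] and sw.log == []
        assert sw.final.r2 == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_log(self, rng):
        tbl = self.null_table(rng)
        tbl["y"] = tbl["y"] + 1.5 * tbl["x3"] - 1.0 * tbl["x7"]
        cands = [f"x{i}" for i in range(10)]
        a = stepwise_regression(tbl, "y", cands)
        b = stepwise_regression(tbl, "y", cands)
        assert a.log == b.log and a.selected == b.selected

    def test_strong_single_predictor_selected(self, rng):
        tbl = self.null_table(rng, n=60, k=12)
        tbl["y"] = 2.0 * tbl["x5"] + rng.normal(0, 1, 60)
        sw = stepwise_regression(tbl, "y", [f"x{i}" for i in range(12)])
        assert "x5" in sw.selected
        assert all(p < 0.10 for p in
                   [sw.final.pvalues[t] for t in sw.selected])

    def test_removal_logged_when_term_loses_significance(self, rng):
        # x0 proxies x1; once x1 enters, x0 should be removed
        n = 80
        x1 = rng.normal(0, 1, n)
        x0 = x1 + rng.normal(0, 0.4, n)
        y = 3.0 * x1 + rng.normal(0, 0.5, n)
        tbl = pd.DataFrame({"x0": x0, "x1": x1, "y": y})
        sw = stepwise_regression(tbl, "y", ["x0", "x1"])
        assert sw.selected == ["x1"]
        actions = [(e["action"], e["term"]) for e in sw.log]
        assert ("remove", "x0") in actions or ("add", "x0") not in actions

    def test_noise_predictor_does_not_raise_r2_adj_in_expectation(self):
        rng = np.random.default_rng(99)
        deltas = []
        for _ in range(500):
            n = 40
            tbl = pd.DataFrame(
                {
                    "x": rng.normal(0, 1, n),
                    "noise": rng.normal(0, 1, n),
                }
            )
            tbl["y"] = 2 * tbl["x"] + rng.normal(0, 1, n)
            base = fit_ols(tbl, "y", ["x"])
            ext = fit_ols(tbl, "y", ["x", "noise"])
            deltas.append(ext.r2_adj - base.r2_adj)
        # expectation is <= 0; allow Monte-Carlo error of the mean
        sem = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert np.mean(deltas) <= 2 * sem


class TestBonferroni:
    def test_flagging_at_twelve_tests(self):
        flags = bonferroni_flags(np.array([0.0001, 0.009, 0.004]), m=12)
        # threshold 0.05/12 ~ 0.00417
        assert list(flags) == [True, False, True]

    def test_m_one_reduces_to_raw_alpha(self):
        flags = bonferroni_flags(np.array([0.049, 0.051]), m=1)
        assert list(flags) == [True, False]


class TestKsNormality:
    def test_normal_sample_passes(self, rng):
        stat, p = ks_normality(rng.normal(0, 1, 500))
        assert p > 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.full(10, 3.0))


def test_encode_design_coding():
    tbl = pd.DataFrame({"sex": ["M", "F"], "side": ["left", "right"]})
    out = encode_design(tbl)
    assert list(out["sex_male"]) == [1.0, 0.0]
    assert list(out["side_right"]) == [0.0, 1.0]
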
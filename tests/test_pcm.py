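"""Linear-model fitting: sequential SS, AICc, variance partition, CV."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoclim import (
    MODEL1,
    MODEL2,
    CollinearityError,
    ModelError,
    ModelSpec,
    compare,
    fit,
    fit_report,
    kfold_cv,
    predict,
    variance_partition,
)

from conftest import ols_oracle


def eq2_frame(n=50, noise_sd=0.0, seed=0):
    """Data following doy = 179.2 + 17.08·pi + 0.02·ppt − 4.14·tmax (+ noise)."""
    rng = np.random.default_rng(seed)
    pi = rng.uniform(1.0, 4.0, n)
    ppt = rng.uniform(50.0, 900.0, n)
    tmax = rng.uniform(5.0, 28.0, n)
    doy = 179.2 + 17.08 * pi + 0.02 * ppt - 4.14 * tmax
    if noise_sd:
        doy = doy + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"doy": doy, "pi": pi, "winter_ppt_mm": ppt, "spring_tmax_c": tmax})


class TestFit:
    def test_noiseless_data_recovers_generating_coefficients(self):
        f = fit(MODEL2, eq2_frame())
        assert f.intercept == pytest.approx(179.2, abs=1e-8)
        assert f.coefficients["pi"][0] == pytest.approx(17.08, abs=1e-8)
        assert f.coefficients["winter_ppt_mm"][0] == pytest.approx(0.02, abs=1e-8)
        assert f.coefficients["spring_tmax_c"][0] == pytest.approx(-4.14, abs=1e-8)
        assert f.r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_term_model_f_equals_t_squared(self, random_regression_data):
        f = fit(ModelSpec(terms=("pi",)), random_regression_data)
        [row] = f.seq_anova
        t_stat = f.coefficients["pi"][0] / f.coefficients["pi"][1]
        assert row.ss == pytest.approx(f.sst - f.sse, rel=1e-10)
        assert row.f_ratio == pytest.approx(t_stat**2, rel=1e-10)

    def test_sequential_ss_conserve_total(self, random_regression_data):
        f = fit(MODEL2, random_regression_data)
        total = sum(r.ss for r in f.seq_anova) + f.sse
        assert total == pytest.approx(f.sst, rel=1e-10)
        assert f.r2 == pytest.approx(1.0 - f.sse / f.sst, rel=1e-12)

    def test_term_order_changes_seq_ss_not_fit(self, random_regression_data):
        a = fit(MODEL2, random_regression_data)
        b = fit(ModelSpec(terms=("spring_tmax_c", "winter_ppt_mm", "pi")),
                random_regression_data)
        # correlated predictors: attribution shifts...
        ss_a = {r.term: r.ss for r in a.seq_anova}
        ss_b = {r.term: r.ss for r in b.seq_anova}
        assert any(abs(ss_a[t] - ss_b[t]) > 1e-6 for t in ss_a)
        # ...but the fitted model is identical
        for term in a.coefficients:
            assert a.coefficients[term][0] == pytest.approx(b.coefficients[term][0], rel=1e-10)
        assert a.sse == pytest.approx(b.sse, rel=1e-12)
        assert a.r2 == pytest.approx(b.r2, rel=1e-12)
        assert a.aicc == pytest.approx(b.aicc, rel=1e-12)

    def test_adding_a_term_never_increases_sse(self, random_regression_data):
        prev = math.inf
        for upto in range(1, 4):
            f = fit(ModelSpec(terms=MODEL2.terms[:upto]), random_regression_data)
            assert f.sse <= prev + 1e-9
            prev = f.sse

    def test_collinear_design_names_dependent_column(self, random_regression_data):
        data = random_regression_data.assign(dup=2.0 * random_regression_data["pi"])
        with pytest.raises(CollinearityError, match="dup"):
            fit(ModelSpec(terms=("pi", "dup")), data)

    def test_insufficient_rows_rejected(self):
        with pytest.raises(ModelError, match="n > p"):
            fit(MODEL2, eq2_frame(n=5))

    def test_missing_values_rejected(self, random_regression_data):
        data = random_regression_data.copy()
        data.loc[0, "pi"] = np.nan
        with pytest.raises(ModelError, match="missing"):
            fit(MODEL2, data)


class TestOracleEquivalence:
    def test_matches_normal_equations_and_nested_refits(self):
        """Coefficients, SEs, seq SS, F and p vs a textbook implementation."""
        rng = np.random.default_rng(7)
        for rep in range(50):
            n = int(rng.integers(10, 31))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n) + X @ rng.normal(size=p)
            terms = tuple(f"x{j}" for j in range(p))
            data = pd.DataFrame({"doy": y, **{t: X[:, j] for j, t in enumerate(terms)}})
            f = fit(ModelSpec(terms=terms), data)

            Xd = np.column_stack([np.ones(n), X])
            oracle = ols_oracle(y, Xd)
            assert f.intercept == pytest.approx(oracle["beta"][0], rel=1e-8, abs=1e-10)
            for j, t in enumerate(terms):
                assert f.coefficients[t][0] == pytest.approx(
                    oracle["beta"][j + 1], rel=1e-8, abs=1e-10)
                assert f.coefficients[t][1] == pytest.approx(
                    oracle["se"][j + 1], rel=1e-8, abs=1e-10)
            assert f.sse == pytest.approx(oracle["sse"], rel=1e-8)

            # sequential SS from scratch: SSE drops along the nested chain
            prev = float(np.sum((y - y.mean()) ** 2))
            for j, row in enumerate(f.seq_anova, start=1):
                sub = ols_oracle(y, Xd[:, : j + 1])
                ss = prev - sub["sse"]
                prev = sub["sse"]
                f_ratio = ss / oracle["mse"]
                assert row.ss == pytest.approx(ss, rel=1e-8, abs=1e-8)
                assert row.f_ratio == pytest.approx(f_ratio, rel=1e-8, abs=1e-8)
                assert row.p_value == pytest.approx(
                    float(stats.f.sf(f_ratio, 1, oracle["df"])), rel=1e-8, abs=1e-12)


class TestAICc:
    def test_matches_closed_form_gaussian_likelihood(self):
        f = fit(MODEL2, eq2_frame(n=20, noise_sd=10.0, seed=3))
        n, k = f.n, len(f.spec.terms) + 2
        llf = -n / 2 * (math.log(2 * math.pi) + math.log(f.sse / n) + 1)
        aic = -2 * llf + 2 * k
        assert f.loglik == pytest.approx(llf, rel=1e-10)
        assert f.aic == pytest.approx(aic, rel=1e-10)
        assert f.aicc == pytest.approx(aic + 2 * k * (k + 1) / (n - k - 1), rel=1e-10)

    def test_correction_is_positive_and_vanishes_with_n(self):
        small = fit(MODEL2, eq2_frame(n=15, noise_sd=10.0, seed=3))
        large = fit(MODEL2, eq2_frame(n=4000, noise_sd=10.0, seed=3))
        assert small.aicc > small.aic
        assert large.aicc - large.aic < 0.05
        assert small.aicc - small.aic > large.aicc - large.aic

    def test_penalty_can_outweigh_an_uninformative_term(self):
        rng = np.random.default_rng(11)
        data = eq2_frame(n=40, noise_sd=15.0, seed=5).assign(junk=rng.normal(size=40))
        base = fit(MODEL2, data)
        bigger = fit(ModelSpec(terms=(*MODEL2.terms, "junk")), data)
        assert bigger.sse <= base.sse
        assert bigger.aicc > base.aicc

    def test_too_small_n_for_aicc_is_an_error(self):
        with pytest.raises(ModelError):
            fit(MODEL2, eq2_frame(n=6, noise_sd=1.0))


class TestVariancePartition:
    def test_proportions_sum_to_one(self, random_regression_data):
        parts = variance_partition(fit(MODEL2, random_regression_data))
        assert sum(p for _, p in parts) == pytest.approx(1.0, rel=1e-12)
        assert [name for name, _ in parts] == ["pi", "winter_ppt_mm", "spring_tmax_c", "error"]

    def test_single_predictor_share_equals_r2(self, random_regression_data):
        f = fit(ModelSpec(terms=("pi",)), random_regression_data)
        parts = dict(variance_partition(f))
        assert parts["pi"] == pytest.approx(f.r2, rel=1e-12)
        assert parts["error"] == pytest.approx(1.0 - f.r2, rel=1e-12)


class TestKFoldCV:
    def test_noiseless_linear_data_scores_one(self):
        cv = kfold_cv(MODEL2, eq2_frame(n=80), k=10, seed=1)
        assert cv.mean_r2 == pytest.approx(1.0, abs=1e-10)
        assert len(cv.per_fold_r2) == 10

    def test_same_seed_reproduces_exactly(self):
        data = eq2_frame(n=60, noise_sd=20.0, seed=2)
        a = kfold_cv(MODEL2, data, k=10, seed=5)
        b = kfold_cv(MODEL2, data, k=10, seed=5)
        assert a.per_fold_r2 == b.per_fold_r2
        c = kfold_cv(MODEL2, data, k=10, seed=6)
        assert a.per_fold_r2 != c.per_fold_r2

    def test_uninformative_predictors_score_near_zero_below_training(self):
        rng = np.random.default_rng(9)
        n = 400
        data = pd.DataFrame({
            "doy": rng.normal(180.0, 30.0, n),
            "pi": rng.uniform(1, 4, n),
            "winter_ppt_mm": rng.uniform(0, 800, n),
            "spring_tmax_c": rng.uniform(5, 25, n),
        })
        cv = kfold_cv(MODEL2, data, k=10, seed=3)
        train_r2 = fit(MODEL2, data).r2
        assert cv.mean_r2 < train_r2
        assert abs(cv.mean_r2) < 0.1  # may be slightly negative

    def test_train_baseline_option(self):
        data = eq2_frame(n=60, noise_sd=20.0, seed=2)
        a = kfold_cv(MODEL2, data, k=5, seed=1, baseline="fold")
        b = kfold_cv(MODEL2, data, k=5, seed=1, baseline="train")
        assert a.per_fold_r2 != b.per_fold_r2

    def test_parameter_validation(self):
        data = eq2_frame(n=15)
        with pytest.raises(ModelError):
            kfold_cv(MODEL2, data, k=1, seed=0)
        with pytest.raises(ModelError):
            kfold_cv(MODEL2, data, k=10, seed=0)


class TestCompare:
    def test_identical_fits_have_zero_deltas(self, random_regression_data):
        f = fit(MODEL2, random_regression_data)
        rep = compare(f, f)
        assert rep.delta_r2 == 0 and rep.delta_aicc == 0
        assert rep.relative_r2_gain == 0 and rep.relative_error_ratio == 0

    def test_published_style_relative_gains(self):
        """R² 0.36 -> 0.47 is a 31% relative gain; error shares 62.9% vs 51.4%
        of total give a 22% higher error variance without the stage term."""
        assert round(100 * (0.47 / 0.36 - 1)) == 31
        f_a = fit(MODEL1, eq2_frame(n=100, noise_sd=25.0, seed=4))
        f_b = fit(MODEL2, eq2_frame(n=100, noise_sd=25.0, seed=4))
        rep = compare(f_a, f_b)
        assert rep.relative_r2_gain == pytest.approx(f_b.r2 / f_a.r2 - 1, rel=1e-12)
        assert rep.relative_error_ratio == pytest.approx(f_a.sse / f_b.sse - 1, rel=1e-12)
        assert rep.delta_aicc == f_b.aicc - f_a.aicc
        assert "more variation explained" in rep.summary()

    def test_mismatched_n_rejected(self):
        f_a = fit(MODEL2, eq2_frame(n=40, noise_sd=5.0))
        f_b = fit(MODEL2, eq2_frame(n=50, noise_sd=5.0))
        with pytest.raises(ModelError):
            compare(f_a, f_b)


class TestReportAndPredict:
    def test_report_contains_anova_and_estimates(self, random_regression_data):
        text = fit_report(fit(MODEL2, random_regression_data))
        for token in ("Seq SS", "F ratio", "R²", "AICc", "Intercept", "Variance partition"):
            assert token in text

    def test_predict_reproduces_fitted_values(self, random_regression_data):
        f = fit(MODEL2, random_regression_data)
        fitted = predict(f, random_regression_data)
        resid = random_regression_data["doy"].to_numpy() - fitted
        assert float(resid @ resid) == pytest.approx(f.sse, rel=1e-10)
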
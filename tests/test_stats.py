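"""Statistics tests: mixed models, curve fits, paired comparison, polynomials."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import statsmodels.api as sm

from nlrpipe.errors import InvalidConfigError
from nlrpipe.nlr import DEFAULT_BIN_CENTERS
from nlrpipe.stats import (
    CurveFitResult,
    adjusted_r2,
    compare_adjr2,
    fit_lmm_absz,
    fit_normal_curve,
    fit_poly_orders,
    fit_square_curve,
    normal_curve,
    orthogonal_poly,
    paired_ttest,
    square_curve,
)

CENTERS = np.array(DEFAULT_BIN_CENTERS)


def _trial_table(rng, n_subjects=6, n_trials=150, intercepts_sd=1.0, slope=0.5, resid=1.0):
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, intercepts_sd)
        absz = np.abs(rng.uniform(-10, 10, n_trials))
        y = 1.0 + u + slope * absz + rng.normal(0, resid, n_trials)
        rows.append(pd.DataFrame(
            {"subject_id": f"S{i:02d}", "source_set": "tail_p200", "abs_z": absz,
             "nlr_raw": y, "retained": True}
        ))
    return pd.concat(rows, ignore_index=True)


class TestLmm:
    def test_recovers_known_slope(self):
        rng = np.random.default_rng(0)
        table = _trial_table(rng, slope=0.5)
        res = fit_lmm_absz(table, subset="tails")
        assert res.slope == pytest.approx(0.5, abs=0.05)
        assert res.ci_lower[1] < 0.5 < res.ci_upper[1]
        assert res.f_absz == pytest.approx(res.t_values[1] ** 2)
        assert res.df == res.n_obs - 2

    def test_zero_group_variance_matches_ols(self):
        rng = np.random.default_rng(1)
        table = _trial_table(rng, intercepts_sd=0.0, slope=0.3)
        res = fit_lmm_absz(table, subset="tails")
        ols = sm.OLS(
            table["nlr_raw"].to_numpy(), sm.add_constant(table["abs_z"].to_numpy())
        ).fit()
        assert res.slope == pytest.approx(ols.params[1], abs=0.02)

    def test_subset_selection(self):
        rng = np.random.default_rng(2)
        table = _trial_table(rng)
        ref = table.copy()
        ref["source_set"] = "reference"
        ref["nlr_raw"] += 100.0  # make subsets distinguishable
        both = pd.concat([table, ref], ignore_index=True)
        res_tails = fit_lmm_absz(both, subset="tails")
        res_ref = fit_lmm_absz(both, subset="reference")
        assert res_ref.estimates[0] - res_tails.estimates[0] == pytest.approx(100.0, abs=1.0)
        with pytest.raises(InvalidConfigError):
            fit_lmm_absz(both, subset="bogus")

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_against_lme4_oracle(self, tmp_path):
        # independent cross-check of the mixed-model machinery on a small table
        rng = np.random.default_rng(3)
        table = _trial_table(rng, n_subjects=5, n_trials=60)
        csv = tmp_path / "trials.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(nlr_raw ~ 1 + abs_z + (1 | subject_id), data = d, REML = TRUE)
            cat(fixef(m)["abs_z"], "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        lme4_slope = float(out.stdout.strip().split()[-1])
        res = fit_lmm_absz(table, subset="tails")
        assert res.slope == pytest.approx(lme4_slope, abs=1e-3)


class TestCurveFits:
    def test_normal_self_consistency(self):
        y = normal_curve(CENTERS, 0.2, 0.0, 2.0, 5.0)
        fit = fit_normal_curve(pd.DataFrame({"bin_center": CENTERS, "mean_negnorm": y}))
        assert fit.converged
        np.testing.assert_allclose(fit.params, [0.2, 0.0, 2.0, 5.0], rtol=1e-4, atol=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-8)

    def test_square_self_consistency(self):
        y = square_curve(CENTERS, 0.0, 4.0, 2.0, 3.0, 0.0)
        fit = fit_square_curve(pd.DataFrame({"bin_center": CENTERS, "mean_negnorm": y}))
        assert fit.converged
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-6)
        pred = square_curve(CENTERS, *fit.params)
        np.testing.assert_allclose(pred, y, atol=1e-5)

    def test_constant_data_degenerate(self):
        y = np.full(CENTERS.size, 0.7)
        fit = fit_normal_curve(pd.DataFrame({"bin_center": CENTERS, "mean_negnorm": y}))
        pred = normal_curve(CENTERS, *fit.params)
        np.testing.assert_allclose(pred, y, atol=1e-6)
        assert fit.r2 == pytest.approx(0.0, abs=1e-6)

    def test_cross_model_step_data(self):
        # hard step: square family should clearly beat the normal family
        y = np.where(np.abs(CENTERS) < 3.0, 1.0, 0.0)
        df = pd.DataFrame({"bin_center": CENTERS, "mean_negnorm": y})
        assert fit_square_curve(df).adj_r2 > fit_normal_curve(df).adj_r2

    def test_cross_model_bell_data(self):
        y = normal_curve(CENTERS, 0.0, 0.0, 1.5, 4.0)
        df = pd.DataFrame({"bin_center": CENTERS, "mean_negnorm": y})
        assert fit_normal_curve(df).adj_r2 > fit_square_curve(df).adj_r2

    def test_large_b_limit_is_step(self):
        z = np.linspace(-10, 10, 401)
        soft = square_curve(z, 0.0, 50.0, 2.0, 3.0, 0.0)
        hard = np.where(np.abs(z) < 3.0, 2.0, 0.0)
        away_from_edges = np.abs(np.abs(z) - 3.0) > 0.3
        np.testing.assert_allclose(soft[away_from_edges], hard[away_from_edges], atol=1e-4)

    def test_too_few_bins(self):
        df = pd.DataFrame({"bin_center": CENTERS[:5], "mean_negnorm": np.zeros(5)})
        with pytest.raises(InvalidConfigError):
            fit_normal_curve(df)


class TestAdjustedR2:
    def test_formula_against_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-5, 5, 12)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 12)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        ss_res = float((res.resid ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        assert adjusted_r2(r2, 12, 1) == pytest.approx(res.rsquared_adj)
        assert adjusted_r2(r2, 12, 1) <= r2


class TestPairedComparison:
    @staticmethod
    def _fits(values, model):
        return [CurveFitResult(model, (0.0,), v, v, 13, True, 1) for v in values]

    def test_identical_vectors(self):
        n = self._fits([0.5, 0.6, 0.7], "normal")
        s = self._fits([0.5, 0.6, 0.7], "square")
        cmp = compare_adjr2(n, s)
        assert cmp.t == 0.0 and cmp.cohen_d == 0.0

    def test_cohen_d_equals_t_over_sqrt_n(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.4, 0.9, 22)
        b = a - rng.uniform(0.1, 0.8, 22)
        cmp = compare_adjr2(self._fits(a, "normal"), self._fits(b, "square"))
        assert cmp.cohen_d == pytest.approx(cmp.t / np.sqrt(22), rel=1e-12)

    def test_reported_pairs_are_internally_consistent(self):
        # published pairs: t(21)=8.1 with d=1.72 and t(18)=6.6 with d=1.52
        assert 8.1 / np.sqrt(22) == pytest.approx(1.72, abs=0.02)
        assert 6.6 / np.sqrt(19) == pytest.approx(1.52, abs=0.02)

    def test_three_pair_closed_form(self):
        diff = np.array([0.3, 0.5, 0.1])
        t, df, p, d = paired_ttest(diff)
        sd = diff.std(ddof=1)
        assert t == pytest.approx(diff.mean() / (sd / np.sqrt(3)))
        assert df == 2
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 2))

    def test_non_converged_pairs_dropped(self):
        n = self._fits([0.5, 0.6, 0.7], "normal")
        s = self._fits([0.1, 0.2, 0.3], "square")
        s[1] = CurveFitResult("square", (np.nan,), np.nan, np.nan, 13, False, 8)
        cmp = compare_adjr2(n, s)
        assert cmp.n_pairs == 2


class TestPolynomials:
    def test_orthonormal_basis(self):
        x = np.tile(np.arange(-2.0, 3.0), 19)
        basis = orthogonal_poly(x, 4)
        gram = basis.T @ basis
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(basis.sum(axis=0), 0.0, atol=1e-10)

    def test_pure_quadratic_identified(self):
        x = np.tile(np.arange(-2.0, 3.0), 4)
        y = -(x ** 2)
        res = fit_poly_orders(pd.DataFrame({"interval_rank": x, "mean_negnorm": y}),
                              orders=(2, 4))
        f4 = res["fits"][4]
        assert abs(f4.term("quadratic")["coef"]) > 1e-6
        assert abs(f4.term("quartic")["coef"]) < 1e-8
        assert abs(f4.term("linear")["coef"]) < 1e-8

    def test_w_shape_prefers_order4_with_negative_terms(self):
        rng = np.random.default_rng(6)
        x = np.tile(np.arange(-2.0, 3.0), 19)
        shape = {-2.0: -1.2, -1.0: 1.0, 0.0: -1.2, 1.0: 1.0, 2.0: -1.2}  # two peaks
        y = np.array([shape[v] for v in x]) + rng.normal(0, 0.15, x.size)
        res = fit_poly_orders(pd.DataFrame({"interval_rank": x, "mean_negnorm": y}))
        assert res["winner"] == 4
        f4 = res["fits"][4]
        assert f4.term("quartic")["coef"] < 0 and f4.term("quartic")["p"] < 0.001
        assert f4.term("quadratic")["coef"] < 0 and f4.term("quadratic")["p"] < 0.001
        assert f4.residual_df == 90  # 95 observations, 5 coefficients

    def test_pure_parabola_prefers_order2(self):
        rng = np.random.default_rng(7)
        x = np.tile(np.arange(-2.0, 3.0), 10)
        y = 1.0 - 0.8 * x ** 2 + rng.normal(0, 0.1, x.size)
        res_aic = fit_poly_orders(pd.DataFrame({"interval_rank": x, "mean_negnorm": y}),
                                  criterion="aic")
        res_bic = fit_poly_orders(pd.DataFrame({"interval_rank": x, "mean_negnorm": y}),
                                  criterion="bic")
        assert res_aic["winner"] == 2
        assert res_bic["winner"] == 2

    def test_aic_bic_consistent_with_loglik(self):
        rng = np.random.default_rng(8)
        x = np.tile(np.arange(-2.0, 3.0), 6)
        y = rng.standard_normal(x.size)
        res = fit_poly_orders(pd.DataFrame({"interval_rank": x, "mean_negnorm": y}))
        f2 = res["fits"][2]
        ols = sm.OLS(y, sm.add_constant(orthogonal_poly(x, 2))).fit()
        # same log-likelihood function used for fitting and for the criteria
        assert f2.aic == pytest.approx(-2 * ols.llf + 2 * 3)
        assert f2.bic == pytest.approx(-2 * ols.llf + np.log(x.size) * 3)

    def test_too_few_observations(self):
        with pytest.raises(InvalidConfigError):
            fit_poly_orders(pd.DataFrame({"interval_rank": [0.0, 1.0, 2.0],
                                          "mean_negnorm": [0.0, 1.0, 2.0]}), orders=(2, 4))
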
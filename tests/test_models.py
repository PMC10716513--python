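"""Mixed-model machinery: ML fits, the adaptive-quadrature logistic GLMM
(cross-checked against lme4::glmer), LRTs, contrasts, and the critical-F
utility."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from popgaze.models import (ModelSpec, critical_f, fit_mixed, lrt_single_term,
                            marginal_contrasts, quadratic_test)


def _simulate_lmm(rng, n_groups=30, n_per=40, beta=(1.0, 0.5, -0.3),
                  re_sd=0.4, resid_sd=1.0):
    g = np.repeat(np.arange(n_groups), n_per)
    x1 = rng.normal(size=g.size)
    x2 = rng.normal(size=g.size)
    u = rng.normal(0, re_sd, n_groups)
    y = beta[0] + beta[1] * x1 + beta[2] * x2 + u[g] + rng.normal(0, resid_sd,
                                                                  g.size)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2,
                         "infant_id": [f"g{i}" for i in g]})


def _simulate_glmm(rng, n_groups=30, n_per=40, beta=(-0.5, 0.8), re_sd=0.7):
    g = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(size=g.size)
    u = rng.normal(0, re_sd, n_groups)
    p = 1 / (1 + np.exp(-(beta[0] + beta[1] * x + u[g])))
    return pd.DataFrame({"y": (rng.random(g.size) < p).astype(int), "x": x,
                         "infant_id": [f"g{i}" for i in g]})


class TestGaussianLMM:
    def test_no_group_variation_reproduces_ols(self, rng):
        df = _simulate_lmm(rng, re_sd=0.0)
        ols = sm.OLS(df["y"], sm.add_constant(df[["x1", "x2"]])).fit()
        # with the random-intercept variance fixed at zero the ML fit *is* OLS
        fixed = fit_mixed(ModelSpec("y", ("x1", "x2")), df, re_var_zero=True)
        np.testing.assert_allclose(fixed.params.to_numpy(),
                                   ols.params.to_numpy(), rtol=1e-6)
        # the free fit sits at the boundary and agrees to estimation noise
        free = fit_mixed(ModelSpec("y", ("x1", "x2")), df)
        np.testing.assert_allclose(free.params.to_numpy(),
                                   ols.params.to_numpy(), atol=5e-3)
        assert free.re_var == pytest.approx(0.0, abs=1e-2)

    def test_recovers_known_coefficients(self, rng):
        df = _simulate_lmm(rng, n_groups=60, n_per=50)
        fit = fit_mixed(ModelSpec("y", ("x1", "x2")), df)
        assert fit.converged
        assert fit.params["x1"] == pytest.approx(0.5, abs=4 * fit.bse["x1"])
        assert fit.re_var == pytest.approx(0.16, rel=0.5)

    def test_matches_statsmodels_mixedlm_reference(self, rng):
        """Independent oracle: statsmodels MixedLM (ML) on a well-behaved
        dataset agrees on coefficients, variances, and log-likelihood."""
        import warnings
        df = _simulate_lmm(rng, n_groups=40, n_per=30, re_sd=0.5)
        fit = fit_mixed(ModelSpec("y", ("x1", "x2")), df)
        import patsy
        yv, X = patsy.dmatrices("y ~ x1 + x2", df, return_type="dataframe")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(np.asarray(yv).ravel(), np.asarray(X),
                             groups=np.asarray(df["infant_id"])
                             ).fit(reml=False)
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   np.asarray(ref.fe_params), atol=1e-5)
        np.testing.assert_allclose(fit.bse.to_numpy(),
                                   np.asarray(ref.bse_fe), rtol=1e-3)
        assert fit.llf == pytest.approx(float(ref.llf), abs=1e-4)
        assert fit.re_var == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3)
        assert fit.scale == pytest.approx(float(ref.scale), rel=1e-3)


class TestLogisticGLMM:
    def test_recovers_known_coefficients(self, rng):
        df = _simulate_glmm(rng, n_groups=60, n_per=60)
        fit = fit_mixed(ModelSpec("y", ("x",), family="binomial"), df)
        assert fit.converged
        assert fit.params["x"] == pytest.approx(0.8, abs=4 * fit.bse["x"])
        assert np.sqrt(fit.re_var) == pytest.approx(0.7, abs=0.25)

    def test_no_heterogeneity_matches_plain_glm(self, rng):
        df = _simulate_glmm(rng, n_groups=40, n_per=40, re_sd=0.0)
        fit = fit_mixed(ModelSpec("y", ("x",), family="binomial"), df)
        glm = sm.GLM(df["y"], sm.add_constant(df["x"]),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   glm.params.to_numpy(), atol=0.02)

    def test_matches_lme4_glmer_reference(self, rng, tmp_path):
        """Independent oracle: lme4::glmer with the same adaptive
        Gauss-Hermite rule must agree on coefficients, the random-intercept
        SD, and the log-likelihood."""
        df = _simulate_glmm(rng, n_groups=25, n_per=30)
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "ref.csv"
        rcode = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|infant_id), data=d, family=binomial,
                       nAGQ=15)
            co <- fixef(m)
            write.csv(data.frame(intercept=co[[1]], slope=co[[2]],
                                 sigma=sqrt(unlist(VarCorr(m))[[1]]),
                                 logLik=as.numeric(logLik(m))),
                      "{out}", row.names=FALSE)
        """)
        res = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(out).iloc[0]
        fit = fit_mixed(ModelSpec("y", ("x",), family="binomial"), df)
        assert fit.params["Intercept"] == pytest.approx(ref["intercept"],
                                                        abs=2e-3)
        assert fit.params["x"] == pytest.approx(ref["slope"], abs=2e-3)
        assert np.sqrt(fit.re_var) == pytest.approx(ref["sigma"], abs=5e-3)
        assert fit.llf == pytest.approx(ref["logLik"], abs=1e-2)


class TestLRT:
    def test_chi2_nonnegative_and_df_counts_parameters(self, rng):
        df = _simulate_lmm(rng)
        df["f3"] = rng.choice(["a", "b", "c"], size=len(df))
        spec = ModelSpec("y", ("x1", "C(f3, Sum)"))
        res = lrt_single_term(spec, "C(f3, Sum)", df)
        assert res.chi2 >= 0.0
        assert res.df == 2          # a 3-level factor drops 2 parameters
        res1 = lrt_single_term(spec, "x1", df)
        assert res1.df == 1

    def test_null_term_gives_large_p_more_often_than_not(self, rng):
        df = _simulate_lmm(rng)
        df["noise"] = rng.normal(size=len(df))
        res = lrt_single_term(ModelSpec("y", ("x1", "noise")), "noise", df)
        assert 0.0 <= res.p <= 1.0

    def test_chi2_invariant_to_contrast_coding(self, rng):
        df = _simulate_lmm(rng)
        df["f3"] = rng.choice(["a", "b", "c"], size=len(df))
        chi_sum = lrt_single_term(ModelSpec("y", ("x1", "C(f3, Sum)")),
                                  "C(f3, Sum)", df).chi2
        chi_trt = lrt_single_term(ModelSpec("y", ("x1", "C(f3)")),
                                  "C(f3)", df).chi2
        assert chi_sum == pytest.approx(chi_trt, abs=1e-4)

    def test_dropping_term_in_retained_interaction_raises(self, rng):
        df = _simulate_lmm(rng)
        spec = ModelSpec("y", ("x1", "x2", "x1:x2"))
        with pytest.raises(ValueError, match="interaction"):
            lrt_single_term(spec, "x1", df)

    def test_identical_models_give_zero_statistic(self, rng):
        df = _simulate_lmm(rng)
        full = fit_mixed(ModelSpec("y", ("x1",)), df)
        again = fit_mixed(ModelSpec("y", ("x1",)), df)
        chi2 = max(0.0, 2 * (full.llf - again.llf))
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert scipy.stats.chi2.sf(chi2, 1) == pytest.approx(1.0, abs=1e-6)


class TestQuadraticTest:
    def test_full_range_trim_equals_untrimmed(self, rng):
        df = _simulate_lmm(rng)
        a = quadratic_test(df, "y", "x1", trim=(0.0, 100.0))
        # untrimmed analysis done by hand on the same centred predictor
        manual = df.copy()
        manual["_xc"] = manual["x1"] - manual["x1"].mean()
        res = lrt_single_term(ModelSpec("y", ("_xc", "I(_xc**2)")),
                              "I(_xc**2)", manual)
        assert a["n"] == len(df)
        assert a["chi2"] == pytest.approx(res.chi2, abs=1e-6)

    def test_detects_injected_curvature(self, rng):
        df = _simulate_lmm(rng, n_groups=40, n_per=50)
        df["y"] = df["y"] - 0.8 * df["x1"] ** 2
        res = quadratic_test(df, "y", "x1")
        assert res["quad_coef"] == pytest.approx(-0.8, abs=0.1)
        assert res["p"] < 1e-6

    def test_empty_after_trim_raises(self, rng):
        df = _simulate_lmm(rng).iloc[:0]
        with pytest.raises(ValueError):
            quadratic_test(df, "y", "x1")


class TestMarginalContrasts:
    def test_binary_factor_contrast_equals_coefficient(self, rng):
        df = _simulate_lmm(rng)
        df["grp"] = rng.choice(["ctl", "trt"], size=len(df))
        fit = fit_mixed(ModelSpec("y", ("grp",)), df)
        res = marginal_contrasts(fit, "grp", "trt", "ctl")
        assert res["contrast"] == pytest.approx(fit.params["grp[T.trt]"])
        assert res["se"] == pytest.approx(fit.bse["grp[T.trt]"], rel=1e-6)

    def test_level_against_itself_is_zero(self, rng):
        df = _simulate_lmm(rng)
        df["grp"] = rng.choice(["ctl", "trt"], size=len(df))
        fit = fit_mixed(ModelSpec("y", ("grp",)), df)
        res = marginal_contrasts(fit, "grp", "trt", "trt")
        assert res["contrast"] == 0.0
        assert res["se"] == 0.0

    def test_interaction_contrast_matches_hand_computed_combination(self, rng):
        """Age contrast at reference ISI levels equals b_age + isi * b_int
        computed by hand from the fitted coefficients."""
        df = _simulate_lmm(rng, n_groups=40, n_per=40)
        df["age10"] = rng.integers(0, 2, len(df))
        df["isi"] = rng.uniform(0.08, 0.4, len(df))
        df["y"] = (df["y"] - 0.09 * df["age10"] + 0.3 * df["age10"] * df["isi"])
        fit = fit_mixed(ModelSpec("y", ("age10", "isi", "age10:isi")), df)
        b_age = fit.params["age10"]
        b_int = fit.params["age10:isi"]
        for isi in (0.08, 0.23, 0.4):
            res = marginal_contrasts(fit, "age10", 1, 0, at={"isi": isi})
            assert res["contrast"] == pytest.approx(b_age + isi * b_int,
                                                    rel=1e-9)

    def test_absent_level_raises(self, rng):
        df = _simulate_lmm(rng)
        df["grp"] = rng.choice(["ctl", "trt"], size=len(df))
        fit = fit_mixed(ModelSpec("y", ("grp",)), df)
        with pytest.raises(ValueError, match="absent"):
            marginal_contrasts(fit, "grp", "nope", "ctl")


class TestCriticalF:
    def test_reported_power_analysis_value(self):
        assert critical_f(0.05, 55, 2420) == pytest.approx(1.34, abs=0.005)

    def test_limit_equals_chi2_quantile(self):
        assert critical_f(0.05, 1, 10 ** 7) == pytest.approx(
            scipy.stats.chi2.isf(0.05, 1), abs=1e-3)

    def test_matches_monte_carlo_quantile(self, rng):
        d1, d2, alpha = 4, 17, 0.1
        draws = (rng.chisquare(d1, 200_000) / d1) / (rng.chisquare(d2, 200_000) / d2)
        mc = np.quantile(draws, 1 - alpha)
        assert critical_f(alpha, d1, d2) == pytest.approx(mc, rel=0.02)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            critical_f(0.0, 2, 10)
        with pytest.raises(ValueError):
            critical_f(0.05, -1, 10)
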
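import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from denshab.rspf import (DEFAULT_PRIOR_SD, ModelSpec, PackComparison,
                          auc_rank, density_response_curves, diagnostics,
                          fit_rspf, pack_heterogeneity_test, predict_rspf,
                          reduce_variables)


def simulate_logistic(n, beta, seed, n_years=5, n_packs=10,
                      year_sd=0.0, pack_slope_sd=0.0, slope_cov="x1"):
    """Bernoulli-logit data with optional year intercepts and pack slopes.

    beta = (intercept, b_x1, b_x2, b_density, b_x1:density).
    """
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    d = rng.standard_normal(n)
    years = rng.integers(0, n_years, n)
    packs = rng.integers(0, n_packs, n)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2 + beta[3] * d + beta[4] * x1 * d
    if year_sd > 0:
        eta = eta + rng.normal(0, year_sd, n_years)[years]
    if pack_slope_sd > 0:
        u = rng.normal(0, pack_slope_sd, n_packs)[packs]
        eta = eta + u * (x1 if slope_cov == "x1" else x2)
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "wolf_density": d,
                         "year": years,
                         "pack_id": pd.Series(packs).map("p{:02d}".format)})


PLAIN_SPEC = ModelSpec(fixed=["x1", "x2"], interactions=["x1"],
                       year_factor=None, pack_factor=None)


class TestFitRSPF:
    def test_zero_variance_reduces_to_plain_logistic(self):
        """With no random structure the fit equals the ordinary logistic MLE."""
        import statsmodels.api as sm
        tab = simulate_logistic(5000, (-2.0, 1.0, -0.5, 0.3, -0.3), seed=0)
        fit = fit_rspf(tab, PLAIN_SPEC)
        X = np.column_stack([np.ones(len(tab)), tab.x1, tab.x2,
                             tab.wolf_density, tab.x1 * tab.wolf_density])
        mle = sm.Logit(tab.y.to_numpy(float), X).fit(disp=0).params
        np.testing.assert_allclose(fit.coef[:5], mle, rtol=1e-4)

    def test_constrained_variances_match_plain_fit(self):
        tab = simulate_logistic(3000, (-1.5, 0.8, -0.4, 0.2, 0.0), seed=1,
                                year_sd=0.5)
        full_spec = ModelSpec(fixed=["x1", "x2"], interactions=["x1"],
                              random_slopes=["x1"])
        pinned = fit_rspf(tab, full_spec, constrain_variances={
            "year": 0.0, "pack:x1": 0.0})
        plain = fit_rspf(tab, PLAIN_SPEC)
        np.testing.assert_allclose(pinned.coef[:5], plain.coef[:5], atol=5e-4)

    def test_recovers_year_variance(self):
        tab = simulate_logistic(20000, (-1.0, 1.0, -0.5, 0.0, 0.0), seed=2,
                                n_years=30, year_sd=0.7)
        spec = ModelSpec(fixed=["x1", "x2"], interactions=[], random_slopes=[])
        fit = fit_rspf(tab, spec)
        assert fit.random_effect_variances()["year"] == pytest.approx(0.49, rel=0.5)

    def test_interaction_recovery_single_seed(self):
        tab = simulate_logistic(20000, (-2.0, 1.0, -0.5, 0.3, -0.3), seed=3)
        fit = fit_rspf(tab, PLAIN_SPEC)
        s = fit.summary()
        row = s.loc["x1:wolf_density"]
        assert row["97.5th percentile"] < 0  # CI excludes zero, right sign
        assert row["mean"] == pytest.approx(-0.3, abs=0.1)

    def test_single_class_rejected(self):
        tab = simulate_logistic(200, (10.0, 0, 0, 0, 0), seed=4)
        tab["y"] = 1
        with pytest.raises(ValueError):
            fit_rspf(tab, PLAIN_SPEC)

    def test_summary_percentile_order(self):
        tab = simulate_logistic(2000, (-1.0, 0.5, 0.0, 0.0, 0.0), seed=5)
        s = fit_rspf(tab, PLAIN_SPEC).summary()
        assert (s["2.5th percentile"] <= s["mean"]).all()
        assert (s["mean"] <= s["97.5th percentile"]).all()
        assert (s["mode"] == s["mean"]).all()

    def test_mixed_model_against_lme4(self, tmp_path):
        """Independent oracle: glmer (Laplace) on the same small dataset."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        tab = simulate_logistic(4000, (-1.0, 0.8, -0.4, 0.0, 0.0), seed=6,
                                n_years=8, year_sd=0.6)
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'tab <- read.csv("{csv}")\n'
            'm <- glmer(y ~ x1 + x2 + (1|year), family=binomial, data=tab)\n'
            'cat(fixef(m), as.data.frame(VarCorr(m))$vcov[1], sep="\\n")\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split("\n")]
        spec = ModelSpec(fixed=["x1", "x2"], interactions=[], density=None,
                         random_slopes=[])
        fit = fit_rspf(tab, spec)
        np.testing.assert_allclose(fit.coef[:3], vals[:3], atol=0.05)
        assert fit.random_effect_variances()["year"] == pytest.approx(vals[3], rel=0.3)


class TestPredict:
    def _fit(self):
        tab = simulate_logistic(1000, (-1.0, 0.5, -0.2, 0.3, -0.1), seed=7)
        return fit_rspf(tab, PLAIN_SPEC)

    def test_all_zero_coefficients_give_half(self):
        fit = self._fit()
        fit.coef[:] = 0.0
        assert predict_rspf(fit, {"x1": 1.0, "x2": -2.0}, density=1.0) == 0.5

    def test_reported_intercept_evaluates_to_small_probability(self):
        # a typical intercept for this design is around -8: at mean covariates
        # and mean density the probability of use is ~3e-4
        fit = self._fit()
        fit.coef[:] = 0.0
        fit.coef[0] = -8.089
        p = predict_rspf(fit, {"x1": 0.0, "x2": 0.0}, density=0.0)
        assert p == pytest.approx(3.07e-4, rel=0.01)

    def test_density_main_effect_linearity(self):
        fit = self._fit()
        fit.coef[:] = 0.0
        fit.coef[fit.fixed_names.index("wolf_density")] = 0.724
        p0 = predict_rspf(fit, {}, density=0.0)
        p1 = predict_rspf(fit, {}, density=1.0)
        lo0 = math.log(p0 / (1 - p0))
        lo1 = math.log(p1 / (1 - p1))
        assert lo1 - lo0 == pytest.approx(0.724, abs=1e-9)

    def test_unknown_pack_rejected(self):
        tab = simulate_logistic(1000, (-1.0, 0.5, -0.2, 0.0, 0.0), seed=8)
        spec = ModelSpec(fixed=["x1", "x2"], interactions=[], random_slopes=["x1"])
        fit = fit_rspf(tab, spec)
        with pytest.raises(KeyError):
            predict_rspf(fit, {"x1": 1.0}, level="pack", pack_id="nope")


class TestDiagnostics:
    def test_auc_equals_bruteforce_concordance(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 500)
        y[0], y[1] = 0, 1
        score = rng.random(500)
        pairs = concord = 0
        for i in np.where(y == 1)[0]:
            for j in np.where(y == 0)[0]:
                pairs += 1
                if score[i] > score[j]:
                    concord += 1
                elif score[i] == score[j]:
                    concord += 0.5
        assert auc_rank(y, score) == pytest.approx(concord / pairs, abs=1e-12)

    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert auc_rank(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_constant_fit_gives_half_auc_zero_r(self):
        tab = simulate_logistic(500, (-1.0, 0.0, 0.0, 0.0, 0.0), seed=10)
        fit = fit_rspf(tab, PLAIN_SPEC)
        fit.fitted = np.full(len(tab), 0.3)
        rep = diagnostics(fit, tab, n_draws=50, seed=0)
        assert rep.auc == 0.5
        assert rep.pearson_r == 0.0
        assert rep.flags

    def test_waic_prefers_true_interaction_model(self):
        tab = simulate_logistic(8000, (-1.5, 1.0, -0.5, 0.3, -0.4), seed=11)
        with_int = fit_rspf(tab, PLAIN_SPEC)
        without = fit_rspf(tab, ModelSpec(fixed=["x1", "x2"], interactions=[],
                                          year_factor=None, pack_factor=None))
        d_with = diagnostics(with_int, tab, n_draws=200, seed=1)
        d_without = diagnostics(without, tab, n_draws=200, seed=1)
        assert d_with.waic <= d_without.waic


class TestDensityResponseCurves:
    def _fit_with(self, b_x, b_xd):
        tab = simulate_logistic(1000, (-1.0, 0.5, -0.2, 0.3, -0.1), seed=12)
        fit = fit_rspf(tab, PLAIN_SPEC)
        fit.coef[:] = 0.0
        fit.coef[fit.fixed_names.index("x1")] = b_x
        fit.coef[fit.fixed_names.index("x1:wolf_density")] = b_xd
        return fit

    def test_effective_slope_arithmetic(self):
        # winter-prey-like values: 0.287 - 0.110 * 2 = 0.067, still positive
        fit = self._fit_with(0.287, -0.110)
        curves = density_response_curves(fit, "x1", density_grid=[2.0])
        slope = curves["effective_slope"].iloc[0]
        assert slope == pytest.approx(0.067, abs=1e-9)
        assert slope > 0

    def test_no_interaction_identical_curves(self):
        fit = self._fit_with(0.5, 0.0)
        curves = density_response_curves(fit, "x1", density_grid=[-2, 0, 2])
        pivot = curves.pivot(index="z", columns="density", values="probability")
        assert pivot.std(axis=1).max() < 1e-12

    def test_sign_switch_density(self):
        fit = self._fit_with(0.4, -0.2)
        curves = density_response_curves(fit, "x1", density_grid=[0.0])
        assert curves.attrs["sign_switch_density"] == pytest.approx(2.0)

    def test_baseline_probability_is_anchor(self):
        fit = self._fit_with(0.6, -0.1)
        curves = density_response_curves(fit, "x1", density_grid=[1.0],
                                         baseline_prob=0.5)
        at_zero = curves[curves["z"] == 0.0]["probability"]
        assert float(at_zero.iloc[0]) == pytest.approx(0.5)


class TestPackHeterogeneity:
    def _fit_with_pack_slopes(self, link=0.0, n_packs=24, seed=13):
        rng = np.random.default_rng(seed)
        tab = simulate_logistic(12000, (-1.0, 0.8, -0.3, 0.0, 0.0), seed=seed,
                                n_packs=n_packs, pack_slope_sd=0.8)
        spec = ModelSpec(fixed=["x1", "x2"], interactions=[], random_slopes=["x1"])
        fit = fit_rspf(tab, spec)
        coefs = fit.pack_coefficients("x1")
        noise = rng.normal(0, 0.5, len(coefs))
        sizes = pd.Series(4.0 + link * (coefs - coefs.mean()) + noise,
                          index=coefs.index).clip(lower=2.0)
        return fit, sizes

    def test_identical_sizes_no_difference(self):
        fit, sizes = self._fit_with_pack_slopes()
        flat = pd.Series(4.0, index=sizes.index)
        rep = pack_heterogeneity_test(fit, flat, "x1")
        assert rep.strong_mean_size == rep.weak_mean_size
        assert rep.rank_sum_pvalue == pytest.approx(1.0)

    def test_detects_simulated_link(self):
        hits = 0
        for seed in range(5):
            fit, sizes = self._fit_with_pack_slopes(link=2.0, n_packs=60,
                                                    seed=20 + seed)
            rep = pack_heterogeneity_test(fit, sizes, "x1")
            hits += (rep.rank_sum_pvalue < 0.05
                     and rep.strong_mean_size > rep.weak_mean_size)
        assert hits >= 4

    def test_rank_sum_matches_pair_counting(self):
        fit, sizes = self._fit_with_pack_slopes(link=1.0, n_packs=20)
        rep = pack_heterogeneity_test(fit, sizes, "x1")
        s = sizes.loc[rep.strong_packs].to_numpy()
        w = sizes.loc[rep.weak_packs].to_numpy()
        u = sum((si > wi) + 0.5 * (si == wi) for si in s for wi in w)
        assert rep.rank_sum_u == pytest.approx(u)

    def test_too_few_packs_rejected(self):
        fit, sizes = self._fit_with_pack_slopes(n_packs=6)
        with pytest.raises(ValueError):
            pack_heterogeneity_test(fit, sizes, "x1")


class TestReduceVariables:
    def test_noise_dropped_signal_kept(self):
        keeps = drops = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 5000
            signal = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            y = (rng.random(n) < expit(-1.0 + 1.2 * signal)).astype(int)
            tab = pd.DataFrame({"y": y, "signal": signal, "noise": noise})
            retained, _ = reduce_variables(tab, ["signal", "noise"], seed=seed)
            keeps += "signal" in retained
            drops += "noise" not in retained
        assert keeps == 5
        assert drops >= 4

    def test_vanishing_penalty_retains_all(self):
        rng = np.random.default_rng(1)
        n = 2000
        a, b = rng.standard_normal((2, n))
        y = (rng.random(n) < expit(0.5 * a + 0.5 * b)).astype(int)
        tab = pd.DataFrame({"y": y, "a": a, "b": b})
        retained, path = reduce_variables(tab, ["a", "b"],
                                          penalty_grid=np.array([1e6]))
        assert retained == ["a", "b"]

    def test_collinear_duplicate_reduced(self):
        rng = np.random.default_rng(2)
        n = 4000
        a = rng.standard_normal(n)
        y = (rng.random(n) < expit(1.0 * a)).astype(int)
        tab = pd.DataFrame({"y": y, "a": a, "a_copy": a})
        retained, _ = reduce_variables(tab, ["a", "a_copy"], seed=0)
        assert len(retained) <= 1 or retained == ["a"]
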
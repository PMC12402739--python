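import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from tabhallu.effects import (EffectEstimate, fit_binomial_glmm,
                              fit_glmm_hr_on_complexity, fit_lmm_tstr_on_hr,
                              hr_spread_filter, nakagawa_r2,
                              retention_percentage, subset_sensitivity)
from tabhallu.errors import FitError, ValidationError


def simulate_glmm(seed, G=12, nobs=100, trials=50, b0=-1.0, b1=0.0, sd=0.5):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, (G, nobs))
    u = rng.normal(0, sd, G)
    y = rng.binomial(trials, expit(b0 + b1 * x + u[:, None]))
    return (y.ravel(), np.full(G * nobs, trials), x.ravel(),
            np.repeat(np.arange(G), nobs))


def simulate_lmm_table(seed, slope=0.0, G=3, nobs=600, noise_sd=0.005,
                       group_sd=0.02, intercept=0.75):
    rng = np.random.default_rng(seed)
    hr = rng.uniform(0, 1, G * nobs)
    group = np.repeat([f"pop{g}" for g in range(G)], nobs)
    u = dict(zip([f"pop{g}" for g in range(G)], rng.normal(0, group_sd, G)))
    tstr = intercept + slope * hr * 100 + np.array([u[g] for g in group]) \
        + rng.normal(0, noise_sd, G * nobs)
    return pd.DataFrame({"generator": "st", "population": group,
                         "hr_mean": hr, "tstr_gbm_mean": tstr})


class TestSpreadFilter:
    def test_constant_hr_population_is_excluded(self):
        t = pd.DataFrame({"generator": "st", "population": "a",
                          "hr_mean": [0.99] * 30})
        filtered, retained = hr_spread_filter(t)
        assert filtered.empty and retained == {}

    def test_uniform_hr_population_is_included(self):
        rng = np.random.default_rng(0)
        hr = rng.uniform(0.3, 0.8, 100)
        t = pd.DataFrame({"generator": "st", "population": "a", "hr_mean": hr})
        filtered, retained = hr_spread_filter(t)
        # direct percentile computation: spread ~ 0.5*0.8 = 0.4 >= 0.25
        direct = np.percentile(hr, 90) - np.percentile(hr, 10)
        assert direct == pytest.approx(0.4, abs=0.05)
        assert len(filtered) == 100
        assert retained == {"st": ["a"]}

    def test_filter_is_per_generator_and_population(self):
        rng = np.random.default_rng(1)
        rows = []
        for gen, pop, lo, hi in [("st", "a", 0.0, 1.0), ("st", "b", 0.9, 1.0),
                                 ("bn", "a", 0.95, 1.0)]:
            rows.append(pd.DataFrame({
                "generator": gen, "population": pop,
                "hr_mean": rng.uniform(lo, hi, 50)}))
        filtered, retained = hr_spread_filter(pd.concat(rows, ignore_index=True))
        assert retained == {"st": ["a"]}
        assert set(filtered["population"]) == {"a"}

    def test_retention_percentage_arithmetic(self):
        assert retention_percentage(8766, 44_478) == pytest.approx(19.71, abs=0.005)
        with pytest.raises(ValidationError):
            retention_percentage(5, 0)


class TestNakagawaR2:
    def test_plug_in_decomposition(self):
        r2m, r2c = nakagawa_r2(0.25, 0.70, 0.05)
        assert r2m == pytest.approx(0.25)
        assert r2c == pytest.approx(0.95)

    def test_zero_random_variance_equates_marginal_and_conditional(self):
        r2m, r2c = nakagawa_r2(0.3, 0.0, 0.7)
        assert r2m == r2c

    def test_ordering_always_holds(self, rng):
        for _ in range(50):
            vf, vr, ve = rng.uniform(0.01, 1, 3)
            r2m, r2c = nakagawa_r2(vf, vr, ve)
            assert 0 <= r2m <= r2c <= 1


class TestBinomialGLMM:
    def test_single_group_is_refused(self):
        with pytest.raises(FitError, match="single group"):
            fit_binomial_glmm([5, 6], [10, 10], [0.0, 1.0], ["a", "a"])

    def test_recovers_generating_fixed_effect(self):
        b1 = np.log(1.10)
        y, n, x, g = simulate_glmm(42, b1=b1)
        fit = fit_binomial_glmm(y, n, x, g)
        lo = fit["beta"][1] - 1.96 * fit["se"][1]
        hi = fit["beta"][1] + 1.96 * fit["se"][1]
        assert lo <= b1 <= hi
        assert fit["beta"][1] == pytest.approx(b1, abs=0.02)
        assert 0.2 < fit["sigma_u"] < 1.2

    def test_null_coverage_is_nominal(self):
        """Wald 95% CIs cover the null in 93-97% of 200 simulations."""
        cover = 0
        for s in range(200):
            y, n, x, g = simulate_glmm(1000 + s, b1=0.0)
            fit = fit_binomial_glmm(y, n, x, g)
            lo = fit["beta"][1] - 1.96 * fit["se"][1]
            hi = fit["beta"][1] + 1.96 * fit["se"][1]
            cover += lo <= 0.0 <= hi
        assert 0.93 <= cover / 200 <= 0.97

    def test_agrees_with_lme4_laplace(self, tmp_path):
        """Independent oracle: the same model fitted by lme4::glmer."""
        y, n, x, g = simulate_glmm(7, b1=np.log(1.10))
        df = pd.DataFrame({"y": y, "n": n, "x": x, "g": g})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(cbind(y, n - y) ~ x + (1 | g), data = d,
                       family = binomial)
            cat(fixef(m)["x"], sqrt(diag(vcov(m)))[2], sep = ",")
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        b1_r, se_r = map(float, proc.stdout.strip().split(","))
        fit = fit_binomial_glmm(y, n, x, g)
        assert fit["beta"][1] == pytest.approx(b1_r, rel=0.02)
        assert fit["se"][1] == pytest.approx(se_r, rel=0.10)

    def test_grouped_interface_reports_odds_ratio(self):
        y, n, x, g = simulate_glmm(3, b1=np.log(1.3))
        table = pd.DataFrame({
            "generator": "st", "population": [f"p{i}" for i in g],
            "complexity": x, "hallucinated_total": y, "trials_total": n})
        est = fit_glmm_hr_on_complexity(table)["st"]
        assert est.effect_scale == "odds-ratio"
        assert est.ci_low <= est.estimate <= est.ci_high
        # a single run checks accuracy, not coverage (coverage has its own
        # 200-simulation test): OR within a few simulation SEs of the truth
        assert est.estimate == pytest.approx(1.3, abs=0.05)
        assert 0 <= est.r2_marginal <= est.r2_conditional <= 1

    def test_single_population_table_is_refused(self):
        table = pd.DataFrame({
            "generator": "st", "population": "only",
            "complexity": np.arange(20.0), "hallucinated_total": 5,
            "trials_total": 10})
        with pytest.raises(FitError, match="single population"):
            fit_glmm_hr_on_complexity(table)


class TestLinearMixedModel:
    def test_recovers_generating_slope(self):
        table = simulate_lmm_table(21, slope=-0.0002)
        est = fit_lmm_tstr_on_hr(table)["st"]
        assert est.ci_low <= -0.0002 <= est.ci_high
        assert est.estimate == pytest.approx(-0.0002, abs=5e-5)

    def test_null_coverage_is_nominal(self):
        cover = 0
        for s in range(200):
            table = simulate_lmm_table(2000 + s, slope=0.0)
            est = fit_lmm_tstr_on_hr(table)["st"]
            cover += est.ci_low <= 0.0 <= est.ci_high
        assert 0.93 <= cover / 200 <= 0.97

    def test_implied_extreme_case_effect(self):
        """A slope of -0.0002 per HR percentage point implies a maximum
        AUROC decrease of 0.02 at 100% HR."""
        table = simulate_lmm_table(5, slope=-0.0002, noise_sd=0.001)
        est = fit_lmm_tstr_on_hr(table)["st"]
        assert abs(est.estimate) * 100 == pytest.approx(0.02, abs=0.005)

    def test_single_population_falls_back_to_ols(self):
        table = simulate_lmm_table(9, slope=-0.0004, G=1)
        est = fit_lmm_tstr_on_hr(table)["st"]
        assert est.method.startswith("OLS")
        assert est.r2_marginal == est.r2_conditional
        assert est.n_groups == 1

    def test_too_few_observations_refused(self):
        table = simulate_lmm_table(1).iloc[:2]
        with pytest.raises(ValidationError, match="3 observations"):
            fit_lmm_tstr_on_hr(table)


class TestSubsetSensitivity:
    def test_fraction_one_reproduces_the_full_fit(self):
        y, n, x, g = simulate_glmm(11, b1=np.log(1.2))
        table = pd.DataFrame({
            "generator": "st", "population": [f"p{i}" for i in g],
            "complexity": x, "hallucinated_total": y, "trials_total": n,
            "hr_mean": y / n, "tstr_gbm_mean": 0.7 - 0.0001 * (y / n) * 100})
        full = fit_glmm_hr_on_complexity(table)["st"]
        sens = subset_sensitivity(table, fractions=(1.0,), seed=0)
        sub = sens[1.0]["hr_on_complexity"]["st"]
        assert sub.estimate == pytest.approx(full.estimate)

    def test_half_subset_estimates_stay_within_full_cis(self):
        y, n, x, g = simulate_glmm(13, b1=np.log(1.15))
        table = pd.DataFrame({
            "generator": "st", "population": [f"p{i}" for i in g],
            "complexity": x, "hallucinated_total": y, "trials_total": n,
            "hr_mean": y / n, "tstr_gbm_mean": 0.7})
        full = fit_glmm_hr_on_complexity(table)["st"]
        sens = subset_sensitivity(table, fractions=(0.5,), seed=1)
        sub = sens[0.5]["hr_on_complexity"]["st"]
        assert full.ci_low * 0.98 <= sub.estimate <= full.ci_high * 1.02
        assert sub.n_obs < full.n_obs

    def test_invalid_fraction_refused(self):
        with pytest.raises(ValidationError):
            subset_sensitivity(simulate_lmm_table(1), fractions=(0.0,))


def test_effect_estimate_invariants_on_simulated_fit():
    table = simulate_lmm_table(30, slope=-0.0001)
    est = fit_lmm_tstr_on_hr(table)["st"]
    assert isinstance(est, EffectEstimate)
    assert est.ci_low <= est.estimate <= est.ci_high
    assert 0 < est.p_value <= 1
    assert 0 <= est.r2_marginal <= est.r2_conditional <= 1
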
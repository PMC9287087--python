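import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enercomp import inference
from enercomp.inference import (
    DesignSpec,
    car1_correlation,
    compare_correlation_structures,
    fit_gls_car1,
    fit_proportion_glm,
    marginal_means,
    simulate_car1_noise,
)


def gaussian_design(y, times=None, groups=None, periods=None):
    n = len(y)
    times = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    groups = np.repeat("G", n) if groups is None else np.asarray(groups)
    periods = groups if periods is None else np.asarray(periods)
    return DesignSpec(
        pd.DataFrame({"value": y, "period": periods, "time": times, "group": groups})
    )


class TestCar1Correlation:
    def test_phi_zero_identity(self):
        R = car1_correlation(np.array([0.0, 1.0, 5.0]), 0.0)
        np.testing.assert_allclose(R, np.eye(3))

    def test_powers(self):
        R = car1_correlation(np.array([0.0, 1.0, 2.0]), 0.5)
        np.testing.assert_allclose(R[0], [1.0, 0.5, 0.25])

    def test_fractional_gap(self):
        R = car1_correlation(np.array([0.0, 2.5]), 0.4)
        assert R[0, 1] == pytest.approx(0.4**2.5, rel=1e-15)

    def test_group_blocks(self):
        R = car1_correlation(
            np.array([0.0, 1.0, 0.0, 1.0]), 0.5, groups=np.array(["a", "a", "b", "b"])
        )
        assert R[0, 1] == 0.5
        assert R[0, 2] == 0.0
        assert R[1, 3] == 0.0

    @pytest.mark.parametrize("phi", [-0.1, 1.0, 1.5])
    def test_invalid_phi(self, phi):
        with pytest.raises(ValueError):
            car1_correlation(np.array([0.0, 1.0]), phi)


def brute_force_ml_loglik(y, X, times, groups, phi):
    """Independent oracle: profile the Gaussian likelihood via a dense
    multivariate-normal density (scipy), maximizing over beta and sigma2."""
    R = np.zeros((len(y), len(y)))
    for i in range(len(y)):
        for j in range(len(y)):
            if groups[i] == groups[j]:
                R[i, j] = phi ** abs(times[i] - times[j]) if i != j else 1.0
    Rinv = np.linalg.inv(R)
    beta = np.linalg.solve(X.T @ Rinv @ X, X.T @ Rinv @ y)
    r = y - X @ beta
    sigma2 = float(r @ Rinv @ r) / len(y)
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=sigma2 * R)


class TestGlsCar1:
    def test_phi_zero_matches_ols(self):
        rng = np.random.default_rng(0)
        periods = np.repeat(["P1", "P2", "P3"], 20)
        y = rng.normal(0, 1, 60) + np.where(periods == "P2", 1.0, 0.0)
        d = gaussian_design(y, groups=periods, periods=periods)
        fit = fit_gls_car1(d, fixed_phi=0.0)
        X, _ = d.matrix()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, ols, atol=1e-8)

    def test_independent_noise_gives_small_phi(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 0.1, 120)
        fit = fit_gls_car1(gaussian_design(y))
        assert fit.phi < 0.15

    def test_profile_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        periods = np.repeat(["P1", "P2"], 15)
        times = np.sort(rng.choice(np.arange(40), 30, replace=False)).astype(float)
        y = rng.normal(0, 1, 30)
        d = gaussian_design(y, times=times, groups=periods, periods=periods)
        X, _ = d.matrix()
        for phi in (0.0, 0.3, 0.7):
            ours = inference._gls_profile(
                y, X, times, np.asarray(periods), phi, "ML"
            )[0]
            oracle = brute_force_ml_loglik(y, X, times, np.asarray(periods), phi)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_equally_spaced_equals_discrete_ar1_gls(self):
        # oracle: explicit R + dense solve at the fitted phi
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 40) + 2.0
        d = gaussian_design(y)
        fit = fit_gls_car1(d)
        X, _ = d.matrix()
        R = car1_correlation(np.arange(40, dtype=float), fit.phi)
        Rinv = np.linalg.inv(R)
        beta = np.linalg.solve(X.T @ Rinv @ X, X.T @ Rinv @ y)
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-8)

    def test_time_shift_within_group_invariant(self):
        rng = np.random.default_rng(4)
        periods = np.repeat(["P1", "P2"], 12)
        times = np.concatenate([np.arange(12.0), np.arange(12.0) + 50])
        y = rng.normal(0, 1, 24)
        d1 = gaussian_design(y, times=times, groups=periods, periods=periods)
        shifted = times.copy()
        shifted[periods == "P2"] += 1000.0
        d2 = gaussian_design(y, times=shifted, groups=periods, periods=periods)
        f1, f2 = fit_gls_car1(d1), fit_gls_car1(d2)
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-10)
        assert f1.phi == pytest.approx(f2.phi, abs=1e-6)

    def test_phi_recovery(self):
        rng = np.random.default_rng(5)
        times = np.arange(300, dtype=float)
        groups = np.repeat("G", 300)
        y = 1.0 + simulate_car1_noise(times, groups, 0.6, 0.1, rng)
        fit = fit_gls_car1(gaussian_design(y))
        assert 0.4 < fit.phi < 0.8

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_gls_car1(gaussian_design(np.array([1.0, 2.0])))

    def test_covariance_psd(self):
        rng = np.random.default_rng(6)
        fit = fit_gls_car1(gaussian_design(rng.normal(0, 1, 50)))
        assert np.all(np.linalg.eigvalsh(fit.coef_covariance) > -1e-12)


def proportion_design(y, periods=None, treatment=None):
    n = len(y)
    periods = np.repeat("P1", n) if periods is None else np.asarray(periods)
    data = pd.DataFrame(
        {
            "value": y,
            "period": periods,
            "time": np.arange(n, dtype=float),
            "group": periods,
        }
    )
    factors = ("period",)
    if treatment is not None:
        data["treatment"] = treatment
        factors = ("period", "treatment")
    return DesignSpec(data, factors=factors)


class TestProportionGlm:
    def test_constant_half_gives_zero_intercept(self):
        fit = fit_proportion_glm(proportion_design(np.full(10, 0.5)))
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_saturated_reproduces_cell_means(self):
        y = np.array([0.92] * 8 + [0.70] * 8)
        periods = np.array(["P1"] * 8 + ["P2"] * 8)
        fit = fit_proportion_glm(proportion_design(y, periods))
        d = proportion_design(y, periods)
        mm = marginal_means(fit, d)
        est = dict(zip(mm.means["level"], mm.means["estimate"]))
        assert est["P1"] == pytest.approx(0.92, abs=1e-6)
        assert est["P2"] == pytest.approx(0.70, abs=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        periods = np.repeat(["P1", "P2", "P3"], 30)
        truth = {"P1": 0.9, "P2": 0.7, "P3": 0.5}
        mu = np.array([truth[p] for p in periods])
        y = np.clip(mu + rng.normal(0, 0.05, len(mu)), 0.01, 0.99)
        d = proportion_design(y, periods)
        fit = fit_proportion_glm(d)
        X, _ = d.matrix()
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-6)
        # dispersion: Pearson chi2 / df
        assert fit.dispersion == pytest.approx(ref.pearson_chi2 / ref.df_resid, rel=1e-6)

    def test_exact_zero_and_one_handled(self):
        y = np.array([0.0, 0.0, 1.0, 1.0, 0.5, 0.5, 0.2, 0.8])
        fit = fit_proportion_glm(proportion_design(y))
        assert np.isfinite(fit.coefficients).all()

    def test_boundary_cell_flagged(self):
        y = np.concatenate([np.zeros(10), np.full(10, 0.5)])
        periods = np.array(["P1"] * 10 + ["P2"] * 10)
        fit = fit_proportion_glm(proportion_design(y, periods))
        assert "boundary" in fit.flags

    def test_fitted_interior(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(0.05, 0.95, 40)
        d = proportion_design(y)
        fit = fit_proportion_glm(d)
        X, _ = d.matrix()
        from scipy.special import expit

        mu = expit(X @ fit.coefficients)
        assert np.all((mu > 0) & (mu < 1))

    def test_out_of_range_response_rejected(self):
        with pytest.raises(ValueError):
            fit_proportion_glm(proportion_design(np.array([0.5, 1.2, 0.3, 0.1])))

    def test_coefficient_recovery_simulation(self):
        # beta-like noise around a logit-linear truth; mean estimate within
        # 3 Monte-Carlo SEs over 60 replicates
        rng = np.random.default_rng(9)
        periods = np.repeat(["P1", "P2"], 40)
        truth = np.array([0.8, 0.4])
        mu = np.where(periods == "P1", *truth)
        ests = []
        for _ in range(60):
            a = mu * 50
            b = (1 - mu) * 50
            y = rng.beta(a, b)
            fit = fit_proportion_glm(proportion_design(y, periods))
            d = proportion_design(y, periods)
            mm = marginal_means(fit, d)
            ests.append(mm.means["estimate"].to_numpy())
        e = np.array(ests)
        mcse = e.std(axis=0) / np.sqrt(len(e))
        # E[beta(a,b)] = mu exactly, so back-transformed cell means target mu
        assert np.all(np.abs(e.mean(axis=0) - truth) < 3 * mcse + 1e-3)


class TestMarginalMeans:
    def test_oneway_gaussian_equals_group_means(self):
        rng = np.random.default_rng(10)
        periods = np.repeat(["P1", "P2", "P3"], 15)
        y = rng.normal(0, 0.3, 45) + np.select(
            [periods == "P1", periods == "P2"], [0.2, 0.6], 0.3
        )
        d = gaussian_design(y, groups=periods, periods=periods)
        fit = fit_gls_car1(d, fixed_phi=0.0)
        mm = marginal_means(fit, d)
        for lev in ("P1", "P2", "P3"):
            est = mm.means.loc[mm.means["level"] == lev, "estimate"].iloc[0]
            assert est == pytest.approx(y[periods == lev].mean(), rel=1e-8)

    def test_equal_cells_contrast_zero(self):
        y = np.array([0.4] * 10 + [0.4] * 10) + np.tile([0.01, -0.01], 10)
        periods = np.array(["P1"] * 10 + ["P2"] * 10)
        d = gaussian_design(y, groups=periods, periods=periods)
        fit = fit_gls_car1(d, fixed_phi=0.0)
        mm = marginal_means(fit, d)
        c = mm.contrasts.iloc[0]
        assert c["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert c["p_adjusted"] == pytest.approx(1.0, abs=1e-9)

    def test_interval_ordering(self):
        rng = np.random.default_rng(11)
        d = gaussian_design(rng.normal(0, 1, 30))
        fit = fit_gls_car1(d)
        mm = marginal_means(fit, d)
        row = mm.means.iloc[0]
        assert row["lower"] <= row["estimate"] <= row["upper"]

    def test_glm_intervals_in_unit_range(self):
        rng = np.random.default_rng(12)
        y = rng.uniform(0.6, 0.95, 30)
        d = proportion_design(y)
        fit = fit_proportion_glm(d)
        mm = marginal_means(fit, d)
        row = mm.means.iloc[0]
        assert 0 < row["lower"] < row["estimate"] < row["upper"] < 1

    def test_two_factor_balanced_average(self):
        rng = np.random.default_rng(13)
        periods = np.tile(np.repeat(["P2", "P3"], 10), 2)
        treatment = np.repeat(["control", "exclosure"], 20)
        y = np.clip(
            0.4
            + 0.2 * (periods == "P2")
            + 0.1 * (treatment == "exclosure")
            + rng.normal(0, 0.02, 40),
            0.01,
            0.99,
        )
        d = proportion_design(y, periods, treatment)
        fit = fit_proportion_glm(d)
        mm = marginal_means(fit, d)
        assert set(mm.means["factor"]) == {"period", "treatment"}
        # treatment contrast exists alongside the period contrast
        assert len(mm.contrasts) == 2

    def test_adjustment_options(self):
        rng = np.random.default_rng(14)
        periods = np.repeat(["P1", "P2", "P3"], 10)
        y = rng.normal(0, 1, 30)
        d = gaussian_design(y, groups=periods, periods=periods)
        fit = fit_gls_car1(d, fixed_phi=0.0)
        p_none = marginal_means(fit, d, adjust="none").contrasts["p_adjusted"]
        p_bonf = marginal_means(fit, d, adjust="bonferroni").contrasts["p_adjusted"]
        p_tukey = marginal_means(fit, d, adjust="tukey").contrasts["p_adjusted"]
        assert np.all(p_bonf >= p_none - 1e-12)
        assert np.all(p_tukey >= p_none - 1e-12)
        with pytest.raises(ValueError):
            marginal_means(fit, d, adjust="holm")

    def test_tukey_matches_studentized_range(self):
        rng = np.random.default_rng(15)
        periods = np.repeat(["P1", "P2", "P3"], 10)
        y = rng.normal(0, 1, 30) + (periods == "P3")
        d = gaussian_design(y, groups=periods, periods=periods)
        fit = fit_gls_car1(d, fixed_phi=0.0)
        mm = marginal_means(fit, d)
        for _, row in mm.contrasts.iterrows():
            expected = stats.studentized_range.sf(
                abs(row["t"]) * np.sqrt(2), 3, fit.df_residual
            )
            assert row["p_adjusted"] == pytest.approx(expected, rel=1e-10)


class TestStructureComparison:
    def test_strong_autocorrelation_selects_car1(self):
        rng = np.random.default_rng(16)
        times = np.arange(80, dtype=float)
        groups = np.repeat("G", 80)
        y = 0.5 + simulate_car1_noise(times, groups, 0.8, 0.2, rng)
        table = compare_correlation_structures(gaussian_design(y))
        assert table.loc[table["selected"], "structure"].iloc[0] == "car1"

    def test_independent_mostly_selects_independence(self):
        rng = np.random.default_rng(17)
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            y = rng.normal(0.5, 0.1, 40)
            table = compare_correlation_structures(gaussian_design(y))
            wins += table.loc[table["selected"], "structure"].iloc[0] == "independence"
        assert wins / n_rep >= 0.8

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            compare_correlation_structures(gaussian_design(np.array([1.0, 2.0, 3.0])))

    def test_aic_consistent_with_loglik(self):
        rng = np.random.default_rng(18)
        table = compare_correlation_structures(gaussian_design(rng.normal(0, 1, 50)))
        for _, row in table.iterrows():
            assert row["AIC"] == pytest.approx(
                -2 * row["loglik"] + 2 * row["n_parameters"]
            )


class TestCoverage:
    def test_interval_coverage_at_study_like_n(self):
        # one-way design, n ~ 120 per period, CAR1 noise; pooled coverage of
        # the 95% period-mean intervals over 400 replicates
        rng = np.random.default_rng(19)
        n_per = 120
        periods = np.repeat(["P1", "P2", "P3"], n_per)
        times = np.concatenate([np.arange(n_per) + 1000 * g for g in range(3)]).astype(float)
        truth = np.array([0.18, 0.58, 0.28])
        mean = np.select([periods == "P1", periods == "P2"], truth[:2], truth[2])
        covered = total = 0
        for _ in range(400):
            y = mean + simulate_car1_noise(times, periods, 0.5, 0.1, rng)
            d = gaussian_design(y, times=times, groups=periods, periods=periods)
            fit = fit_gls_car1(d)
            mm = marginal_means(fit, d)
            lo = mm.means["lower"].to_numpy()
            hi = mm.means["upper"].to_numpy()
            covered += int(np.sum((lo <= truth) & (truth <= hi)))
            total += 3
        assert 0.93 <= covered / total <= 0.97
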
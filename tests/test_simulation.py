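"""Unit tests for the omitted-variable-bias Monte Carlo arm."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

import pcurvelab as pl
from pcurvelab.errors import (
    CollinearityError,
    DegenerateSampleError,
    InvalidParameterError,
    NoSolutionError,
)


class TestExpectedOvb:
    @pytest.mark.parametrize(
        "gamma,cov,var,expected",
        [
            (1.0, 0.2, 1.0, 0.2),
            (0.0, 0.2, 1.0, 0.0),
            (0.5, 0.2, 1.0, 0.1),
            (2.0, 0.3, 2.0, 0.3),
        ],
    )
    def test_bias_formula(self, gamma, cov, var, expected):
        assert pl.expected_ovb(gamma, cov, var) == pytest.approx(expected)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            pl.expected_ovb(1.0, 0.2, 0.0)

    def test_matches_monte_carlo_slope_mean(self):
        """Mean fitted slope of the short regression equals gamma*cov/var."""
        gamma, n, reps = 0.5, 1000, 4000
        spec = pl.DGPSpec(beta_star=0.0, gamma_max=gamma)
        rng = np.random.default_rng(21)
        slopes = np.array(
            [
                pl.fit_omitted_regression(pl.draw_sample(spec, gamma, n, rng)).coefficient
                for _ in range(reps)
            ]
        )
        sem = slopes.std(ddof=1) / math.sqrt(reps)
        assert abs(slopes.mean() - pl.expected_ovb(gamma, 0.2, 1.0)) < 3 * sem


class TestCalibrateGammaMax:
    def test_null_target_gives_null_gamma(self):
        assert pl.calibrate_gamma_max(0.0, 0.2) == 0.0

    def test_known_root(self):
        assert pl.calibrate_gamma_max(0.1, 0.2) == pytest.approx(1 / math.sqrt(3))

    @pytest.mark.parametrize("rho", [0.005, 0.01, 0.05, 0.1, 0.15])
    def test_matches_numerical_root(self, rho):
        """Closed form equals the brentq root of cov*g/sqrt(1+g^2) = rho."""
        gamma = pl.calibrate_gamma_max(rho, 0.2)
        root = brentq(lambda g: 0.2 * g / math.sqrt(1 + g * g) - rho, 0.0, 1e6)
        assert gamma == pytest.approx(root, abs=1e-9)

    def test_monotone_in_target(self):
        gammas = [pl.calibrate_gamma_max(r, 0.2) for r in (0.01, 0.05, 0.1, 0.19)]
        assert gammas == sorted(gammas)

    def test_unattainable_target_rejected(self):
        with pytest.raises(NoSolutionError):
            pl.calibrate_gamma_max(0.2, 0.2)
        with pytest.raises(NoSolutionError):
            pl.calibrate_gamma_max(0.1, 0.0)
        with pytest.raises(InvalidParameterError):
            pl.calibrate_gamma_max(-0.1, 0.2)

    def test_realized_correlation_matches_target(self):
        """Simulating at the calibrated gamma reproduces the target corr."""
        gamma = pl.calibrate_gamma_max(0.1, 0.2)
        spec = pl.DGPSpec(beta_star=0.0, gamma_max=gamma)
        s = pl.draw_sample(spec, gamma, 10**6, np.random.default_rng(5))
        assert np.corrcoef(s.y, s.x)[0, 1] == pytest.approx(0.1, abs=5e-3)


class TestDrawSample:
    def test_null_coefficients_make_outcome_pure_noise(self):
        spec = pl.DGPSpec(beta_star=0.0, gamma_max=0.0)
        s = pl.draw_sample(spec, 0.0, 100, np.random.default_rng(0))
        np.testing.assert_array_equal(s.y, s.epsilon)

    def test_sample_covariance_converges(self):
        spec = pl.DGPSpec(gamma_max=1.0)
        s = pl.draw_sample(spec, 1.0, 10**6, np.random.default_rng(1))
        assert np.corrcoef(s.x, s.z)[0, 1] == pytest.approx(0.2, abs=5e-3)

    def test_identical_seeds_identical_samples(self):
        spec = pl.DGPSpec(gamma_max=1.0)
        a = pl.draw_sample(spec, 0.7, 500, np.random.default_rng(9))
        b = pl.draw_sample(spec, 0.7, 500, np.random.default_rng(9))
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.z, b.z)

    def test_degenerate_size_rejected(self):
        spec = pl.DGPSpec(gamma_max=0.0)
        with pytest.raises(DegenerateSampleError):
            pl.draw_sample(spec, 0.0, 2, np.random.default_rng(0))
        with pytest.raises(InvalidParameterError):
            pl.draw_sample(spec, -0.5, 100, np.random.default_rng(0))


class TestFitOmittedRegression:
    def test_perfect_fit_recovers_exact_slope(self):
        x = np.arange(10.0)
        s = pl.SimulatedSample(x=x, z=x, epsilon=np.zeros(10), y=2 * x, gamma=0.0, n=10)
        fit = pl.fit_omitted_regression(s)
        assert fit.coefficient == pytest.approx(2.0, abs=1e-12)
        assert fit.p_value == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_closed_form_on_fixture(self):
        """Slope, SE, t and p agree with hand-computed OLS on 6 points."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1, 11.9])
        fit = pl.simple_slope(x, y)
        # independent textbook computation
        xb, yb = x.mean(), y.mean()
        sxx = np.sum((x - xb) ** 2)
        slope = np.sum((x - xb) * (y - yb)) / sxx
        resid = y - yb - slope * (x - xb)
        se = math.sqrt(resid @ resid / (len(x) - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), len(x) - 2)
        assert fit.coefficient == pytest.approx(slope, abs=1e-12)
        assert fit.std_error == pytest.approx(se, abs=1e-12)
        assert fit.t_stat == pytest.approx(t, abs=1e-10)
        assert fit.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        fit = pl.simple_slope(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.coefficient == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.std_error == pytest.approx(ref.bse[1], abs=1e-10)
        assert fit.p_value == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_constant_regressor_rejected(self):
        s = pl.SimulatedSample(
            x=np.ones(10), z=np.ones(10), epsilon=np.zeros(10),
            y=np.arange(10.0), gamma=0.0, n=10,
        )
        with pytest.raises(CollinearityError):
            pl.fit_omitted_regression(s)

    def test_point_mass_gamma_reproduces_expected_bias(self):
        """At gamma=1 the slope mean converges to 0.2 (cov_xz/var_x)."""
        spec = pl.DGPSpec(beta_star=0.0, gamma_max=1.0)
        rng = np.random.default_rng(17)
        slopes = np.array(
            [
                pl.fit_omitted_regression(pl.draw_sample(spec, 1.0, 1000, rng)).coefficient
                for _ in range(4000)
            ]
        )
        sem = slopes.std(ddof=1) / math.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.2) < 3 * sem


class TestRunMonteCarlo:
    def test_null_rejection_rate_near_alpha(self, null_mc_pvalues):
        """Exact null: 5% of p-values fall below 0.05, within binomial error."""
        share = pl.significant_share(null_mc_pvalues, 0.05)
        tol = 3 * math.sqrt(0.05 * 0.95 / len(null_mc_pvalues))
        assert abs(share - 0.05) < tol

    def test_null_pvalues_uniform(self, null_mc_pvalues):
        """Exact null: the p-value distribution is Uniform[0,1] (KS test)."""
        assert stats.kstest(null_mc_pvalues, "uniform").pvalue > 0.001

    def test_same_seed_identical_output(self):
        spec = pl.DGPSpec(rho_max=0.05, n_min=50, n_max=200)
        a = pl.monte_carlo_table(spec, 300, 5)
        b = pl.monte_carlo_table(spec, 300, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_power_increases_with_max_sample_size(self):
        """Bias persists as n grows, so significance rises with n_max."""
        shares = {}
        for n_max in (100, 10_000):
            spec = pl.DGPSpec(rho_max=0.1, n_min=50, n_max=n_max)
            fr = pl.monte_carlo_table(spec, 10_000, 3)
            shares[n_max] = pl.significant_share(fr["p_value"])
        assert shares[10_000] > shares[100]

    def test_bias_oracle_over_gamma_grid(self):
        """MC slope means track gamma*cov/var across fixed gamma values."""
        rng = np.random.default_rng(29)
        spec = pl.DGPSpec(beta_star=0.0, gamma_max=1.0)
        for gamma in (0.0, 0.25, 0.5, 1.0):
            slopes = np.array(
                [
                    pl.fit_omitted_regression(
                        pl.draw_sample(spec, gamma, 500, rng)
                    ).coefficient
                    for _ in range(3000)
                ]
            )
            sem = slopes.std(ddof=1) / math.sqrt(len(slopes))
            assert abs(slopes.mean() - pl.expected_ovb(gamma)) < 3 * sem

    def test_invalid_iteration_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            pl.run_monte_carlo(pl.DGPSpec(gamma_max=0.0), 0, 1)

    def test_spec_validation(self):
        with pytest.raises(InvalidParameterError):
            pl.DGPSpec(cov_xz=1.0)
        with pytest.raises(InvalidParameterError):
            pl.DGPSpec(n_min=0)
        with pytest.raises(InvalidParameterError):
            pl.DGPSpec(gamma_max=0.5, rho_max=0.1)
        with pytest.raises(InvalidParameterError):
            pl.DGPSpec(gamma_max=-1.0)
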
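"""Limit uncertainty: Monte Carlo covariance, truncated-normal intervals,
and the Hotelling-style F-test."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from ndes import (
    NDESParameters,
    SyntheticConfig,
    calibrate_sigma_from_interval,
    extinction_test_battery,
    fit_ndes,
    fixed_point,
    generate_plot_pairs,
    limit_f_test,
    mc_limit_covariance,
    truncnorm_interval,
)
from ndes.estimation import NDESFit
from ndes.inference import LimitEstimate


def make_fit(T, cov, n=100):
    return NDESFit(T=T, cov=np.asarray(cov, float), r2=(0.9, 0.9, 0.9),
                   n_pairs=n, objective=0.1, converged=True)


@pytest.fixture(scope="module")
def t2019_fit(t2019):
    cov = np.zeros((6, 6))
    np.fill_diagonal(cov, [1e-4, 1e-2, 1e-4, 1e-4, 1e-4, 1e-4])
    return make_fit(t2019, cov)


class TestMonteCarloLimitCovariance:
    def test_zero_parameter_covariance_gives_zero_limit_covariance(self, t2019):
        fit = make_fit(t2019, np.zeros((6, 6)))
        rng = np.random.default_rng(0)
        inits = rng.dirichlet(np.ones(3), size=50)
        est = mc_limit_covariance(fit, inits, seed=1)
        # every draw equals the point estimate and every start reaches the
        # same attractor, so the sample covariance vanishes
        assert np.max(np.abs(est.sigma_star)) < 1e-20
        np.testing.assert_allclose(est.y_star, fixed_point(t2019).y_star, atol=1e-9)

    def test_covariance_entries_sum_to_zero(self, t2019_fit):
        rng = np.random.default_rng(3)
        est = mc_limit_covariance(t2019_fit, rng.dirichlet(np.ones(3), size=100), seed=4)
        assert abs(est.sigma_star.sum()) < 1e-10
        np.testing.assert_allclose(est.sigma_star.sum(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(est.sigma_star.sum(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(est.sigma_star, est.sigma_star.T, atol=1e-15)

    def test_matches_independent_loop_oracle_draw_for_draw(self, t2019):
        """Independently coded draw/iterate loop with the same seed and
        draw order must reproduce the covariance exactly."""
        cov = np.zeros((6, 6))
        np.fill_diagonal(cov, [0, 0, 1e-4, 1e-4, 1e-4, 1e-4])
        fit = make_fit(t2019, cov)
        rng = np.random.default_rng(12)
        inits = rng.dirichlet(np.ones(3), size=500)
        seed = 99
        est = mc_limit_covariance(fit, inits, seed=seed, tol=1e-10)

        # oracle: plain loop, same generator sequence and PSD square root
        w, V = np.linalg.eigh(cov)
        chol = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        gen = np.random.default_rng(seed)
        mean = fit.T.to_array()
        limits = []
        for y in inits:
            T0 = mean + chol @ gen.standard_normal(6)
            y = np.asarray(y)
            while True:
                t1, t2, t3, t4, t5, t6 = T0
                a = np.array([0.0, np.log(t1) + t3 * y[0] + t4 * y[1],
                              np.log(t2) + t5 * y[0] + t6 * y[1]])
                a -= a.max()
                wgt = np.exp(a)
                fy = wgt / wgt.sum()
                if np.max(np.abs(fy - y)) <= 1e-10:
                    y = fy
                    break
                y = fy
            limits.append(y)
        oracle_cov = np.cov(np.array(limits), rowvar=False, ddof=1)
        np.testing.assert_array_equal(est.sigma_star, oracle_cov)
        assert est.redraws == 0

    def test_too_wide_covariance_is_an_error(self, t2019):
        cov = np.zeros((6, 6))
        cov[0, 0] = 25.0  # sd 5 on t1=1.5 -> most draws nonpositive
        fit = make_fit(t2019, cov)
        with pytest.raises(RuntimeError, match="(redraws|invalid)"):
            mc_limit_covariance(fit, [np.full(3, 1 / 3)] * 50, seed=0)

    def test_empty_initials_rejected(self, t2019_fit):
        with pytest.raises(ValueError, match="at least one"):
            mc_limit_covariance(t2019_fit, [], seed=0)


class TestTruncatedNormalInterval:
    def test_reproduces_published_interval_table(self):
        # sigma calibrated to each 95% interval must reproduce the
        # published 99% endpoints
        rows = [
            (0.0408, (0.0354, 0.0461), (0.0337, 0.0478)),
            (0.0642, (0.0561, 0.0723), (0.0536, 0.0749)),
            (0.8950, (0.8847, 0.9053), (0.8815, 0.9086)),
        ]
        for point, iv95, iv99 in rows:
            sigma = calibrate_sigma_from_interval(point, *iv95, level=0.95)
            got = truncnorm_interval(point, sigma, 0.99)
            assert abs(got.lower - iv99[0]) < 5e-4
            assert abs(got.upper - iv99[1]) < 5e-4

    def test_tiny_sigma_collapses_to_point(self):
        iv = truncnorm_interval(0.3, 1e-12, 0.95)
        assert abs(iv.lower - 0.3) < 1e-9 and abs(iv.upper - 0.3) < 1e-9

    def test_matches_quadrature_oracle(self):
        """Endpoints against brute-force integration of the truncated
        density (normal pdf renormalized to [0, 1])."""
        point, sigma, level = 0.5, 0.2, 0.95
        tau, _ = integrate.quad(lambda y: stats.norm.pdf(y, point, sigma), 0, 1)

        def cdf(x):
            v, _ = integrate.quad(lambda y: stats.norm.pdf(y, point, sigma), 0, x)
            return v / tau

        q = (1 - level) / 2
        lo = optimize.brentq(lambda x: cdf(x) - q, 0, 1, xtol=1e-12)
        hi = optimize.brentq(lambda x: cdf(x) - (1 - q), 0, 1, xtol=1e-12)
        iv = truncnorm_interval(point, sigma, level)
        assert abs(iv.lower - lo) < 1e-8 and abs(iv.upper - hi) < 1e-8

    def test_far_from_truncation_agrees_with_plain_normal(self):
        point, sigma = 0.5, 0.02  # bounds ~25 sigma away
        iv = truncnorm_interval(point, sigma, 0.95)
        lo, hi = stats.norm.interval(0.95, loc=point, scale=sigma)
        assert abs(iv.lower - lo) < 1e-10 and abs(iv.upper - hi) < 1e-10

    def test_width_monotone_in_level_and_sigma(self):
        widths_lvl = [
            (lambda iv: iv.upper - iv.lower)(truncnorm_interval(0.3, 0.05, lvl))
            for lvl in (0.5, 0.8, 0.9, 0.95, 0.99)
        ]
        assert np.all(np.diff(widths_lvl) > 0)
        widths_sig = [
            (lambda iv: iv.upper - iv.lower)(truncnorm_interval(0.3, s, 0.95))
            for s in (0.01, 0.05, 0.1, 0.2)
        ]
        assert np.all(np.diff(widths_sig) > 0)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            truncnorm_interval(0.5, 0.0, 0.95)
        with pytest.raises(ValueError, match="point"):
            truncnorm_interval(1.5, 0.1, 0.95)
        with pytest.raises(ValueError, match="level"):
            truncnorm_interval(0.5, 0.1, 1.0)


class TestLimitFTest:
    def test_null_at_point_estimate_gives_zero_statistic(self):
        res = limit_f_test((0.3, 0.2), (0.3, 0.2), np.diag([0.01, 0.01]), 100)
        assert res.F == 0.0 and res.p_value == 1.0

    def test_hand_computed_case(self):
        # d = (0.3, 0.2), S = diag(0.01): quadratic form 0.09/0.01 + 0.04/0.01
        # = 13; F = (98/198) * 13
        res = limit_f_test((0.3, 0.2), (0.0, 0.0), np.diag([0.01, 0.01]), 100)
        np.testing.assert_allclose(res.F, 98 / 198 * 13, rtol=1e-12)
        assert res.df1 == 2 and res.df2 == 98
        np.testing.assert_allclose(res.p_value, stats.f.sf(98 / 198 * 13, 2, 98))

    def test_scale_invariance(self):
        d, S = np.array([0.1, -0.05]), np.array([[4e-4, -1e-4], [-1e-4, 9e-4]])
        base = limit_f_test(d, (0, 0), S, 50)
        c = 7.3
        scaled = limit_f_test(c * d, (0, 0), c**2 * S, 50)
        np.testing.assert_allclose(scaled.F, base.F, rtol=1e-12)

    def test_singular_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            limit_f_test((0.3, 0.2), (0, 0), np.zeros((2, 2)), 100)

    def test_extinction_hypotheses_rejected_at_published_scale(self, t2019):
        """With a limit covariance of the magnitude implied by the
        published interval widths (sd of a few 1e-3) and n = 1712 plots,
        all three extinction hypotheses are overwhelmingly rejected."""
        sd = np.array([0.00273, 0.00413, 0.00526])  # from the 95% intervals
        corr = -0.3
        S = np.diag(sd**2)
        S[0, 1] = S[1, 0] = corr * sd[0] * sd[1]
        S[0, 2] = S[2, 0] = corr * sd[0] * sd[2]
        S[1, 2] = S[2, 1] = corr * sd[1] * sd[2]
        est = LimitEstimate(
            y_star=np.array([0.0408, 0.0642, 0.8950]),
            sigma_star=S, n=1712, draws=1712, redraws=0, seed=0,
        )
        tests = extinction_test_battery(est)
        assert set(tests) == {"pine_extinct", "fir_extinct", "both_extinct"}
        for res in tests.values():
            assert res.F > 0 and res.p_value < 1e-6


class TestEndToEndCoverage:
    def test_truncnorm_limit_interval_covers_truth(self):
        """Full pipeline (simulate -> fit -> MC limit -> interval): the
        95% interval should cover the true limit component in at least
        90% of seeded replicates."""
        from ndes import DEFAULT_T_TRUE

        true_limit = fixed_point(DEFAULT_T_TRUE).y_star
        reps = 200
        hits = np.zeros(3)
        for rep in range(reps):
            cfg = SyntheticConfig(n_plots=200, noise_concentration=200.0,
                                  seed=40_000 + rep)
            pairs = generate_plot_pairs(cfg)
            fit = fit_ndes(pairs)
            est = mc_limit_covariance(fit, [p.y1 for p in pairs],
                                      seed=50_000 + rep, tol=1e-9)
            for i in range(3):
                iv = truncnorm_interval(float(est.y_star[i]),
                                        float(np.sqrt(est.sigma_star[i, i])), 0.95)
                hits[i] += iv.lower <= true_limit[i] <= iv.upper
        assert np.all(hits / reps >= 0.90)
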
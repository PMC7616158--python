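"""CUE-GMM estimation: objective, fits, overdispersion, heterogeneity test."""
import numpy as np
import pytest
from scipy import optimize, stats

from pcgmm.datatypes import ValidationError
from pcgmm.estimation import (
    cue_objective,
    fit_robust,
    fit_unrobust,
    heterogeneity_test,
    wald_ci,
)

from conftest import make_reduction


def random_reduction(rng, p=6, k=2, noise=0.0, scale=0.05):
    """A small PC-scale problem with known theta and controllable misfit."""
    beta_x_pc = rng.normal(size=(p, k))
    theta = rng.normal(size=k)
    beta_y_pc = beta_x_pc @ theta + noise * rng.normal(size=p)
    omega_yy = scale * np.diag(0.5 + rng.random(p))
    omega_xx = np.zeros((k, k, p, p))
    for a in range(k):
        omega_xx[a, a] = scale * np.diag(0.5 + rng.random(p))
    return make_reduction(beta_x_pc, beta_y_pc, omega_yy=omega_yy, omega_xx=omega_xx), theta


class TestCueObjective:
    def test_zero_at_exact_solution(self, rng):
        red, theta = random_reduction(rng, noise=0.0)
        assert cue_objective(theta, 0.0, red) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_quadratic_form(self):
        # K=1, p=2, diagonal covariances: Q = sum g_i^2 / (w_y_i + t^2 w_x_i)
        beta_x_pc = np.array([[1.0], [2.0]])
        beta_y_pc = np.array([0.5, 0.1])
        omega_yy = np.diag([0.04, 0.09])
        omega_xx = np.zeros((1, 1, 2, 2))
        omega_xx[0, 0] = np.diag([0.01, 0.02])
        red = make_reduction(beta_x_pc, beta_y_pc, omega_yy=omega_yy, omega_xx=omega_xx)
        t = 0.3
        g = beta_y_pc - beta_x_pc[:, 0] * t
        expected = g[0] ** 2 / (0.04 + t**2 * 0.01) + g[1] ** 2 / (0.09 + t**2 * 0.02)
        assert cue_objective([t], 0.0, red) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_non_increasing_in_kappa2(self, seed):
        rng = np.random.default_rng(seed)
        red, theta = random_reduction(rng, noise=0.3)
        t = theta + 0.2  # ensure g != 0
        qs = [cue_objective(t, k2, red) for k2 in (0.0, 0.5, 1.0, 5.0, 50.0)]
        assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))
        assert qs[0] > 0

    def test_underidentified_rejected(self, rng):
        red, theta = random_reduction(rng, p=2, k=2)
        with pytest.raises(ValidationError):
            cue_objective(theta, 0.0, red)


class TestFitUnrobust:
    def test_exact_proportional_data_recovers_theta(self):
        p = 5
        beta_x_pc = np.linspace(0.5, 2.0, p).reshape(p, 1)
        theta_true = 0.7
        red = make_reduction(beta_x_pc, theta_true * beta_x_pc[:, 0],
                             omega_yy=0.01 * np.eye(p),
                             omega_xx=0.01 * np.eye(p)[None, None] * np.ones((1, 1, 1, 1)))
        fit = fit_unrobust(red)
        assert fit.theta[0] == pytest.approx(theta_true, abs=1e-6)
        assert fit.q_stat == pytest.approx(0.0, abs=1e-8)
        assert fit.converged

    def test_matches_grid_search_oracle(self, rng):
        red, _ = random_reduction(rng, p=4, k=2, noise=0.15)
        fit = fit_unrobust(red)
        grid = np.linspace(fit.theta - 0.3, fit.theta + 0.3, 61)
        best_q, best_t = np.inf, None
        for t1 in grid[:, 0]:
            for t2 in grid[:, 1]:
                q = cue_objective([t1, t2], 0.0, red)
                if q < best_q:
                    best_q, best_t = q, (t1, t2)
        assert fit.q_stat <= best_q + 1e-10
        np.testing.assert_allclose(fit.theta, best_t, atol=1.5e-2)  # grid spacing 1e-2

    def test_ivw_closed_form_with_fixed_weighting(self, rng):
        # no exposure uncertainty -> Omega constant -> CUE = GLS/IVW closed form
        p = 7
        beta_x_pc = rng.normal(size=(p, 1))
        beta_y_pc = 0.4 * beta_x_pc[:, 0] + 0.1 * rng.normal(size=p)
        omega_yy = np.diag(0.02 + 0.05 * rng.random(p))
        red = make_reduction(beta_x_pc, beta_y_pc, omega_yy=omega_yy,
                             omega_xx=np.zeros((1, 1, p, p)))
        fit = fit_unrobust(red)
        w = 1.0 / np.diag(omega_yy)
        ivw = np.sum(w * beta_x_pc[:, 0] * beta_y_pc) / np.sum(w * beta_x_pc[:, 0] ** 2)
        assert fit.theta[0] == pytest.approx(ivw, abs=1e-6)

    def test_identification_error(self, rng):
        red, _ = random_reduction(rng, p=2, k=2)
        with pytest.raises(ValidationError):
            fit_unrobust(red)


class TestFitRobust:
    def test_floor_rule_reduces_to_unrobust(self, rng):
        # tiny residual noise: Q(theta,0) << df -> kappa2 floored at 0
        red, _ = random_reduction(rng, p=8, k=2, noise=1e-4)
        fr = fit_robust(red)
        fu = fit_unrobust(red)
        assert fr.kappa2 == 0.0
        np.testing.assert_allclose(fr.theta, fu.theta, atol=1e-8)
        np.testing.assert_allclose(fr.se_theta, fu.se_theta, rtol=1e-8)

    def test_kappa2_matches_independent_root_finder(self, rng):
        red, _ = random_reduction(rng, p=10, k=2, noise=0.6)
        fr = fit_robust(red)
        assert fr.kappa2 > 0
        df = red.p - 2
        f = lambda k2: cue_objective(fr.theta, k2, red) - df
        assert f(0.0) > 0
        root = optimize.brentq(f, 0.0, 1e6, xtol=1e-12)
        assert fr.kappa2 == pytest.approx(root, rel=1e-5)
        # at the solution the objective sits exactly at its null expectation
        assert cue_objective(fr.theta, fr.kappa2, red) == pytest.approx(df, rel=1e-6)

    def test_robust_se_dominates_when_overdispersed(self, rng):
        red, _ = random_reduction(rng, p=10, k=2, noise=0.6)
        fr = fit_robust(red)
        fu = fit_unrobust(red)
        assert fr.kappa2 > 0
        assert np.all(fr.se_theta >= fu.se_theta - 1e-12)

    def test_needs_extra_degree_of_freedom(self, rng):
        red, _ = random_reduction(rng, p=3, k=2)
        with pytest.raises(ValidationError):
            fit_robust(red)


class TestHeterogeneityTest:
    def test_zero_statistic_gives_pvalue_one(self, rng):
        red, theta = random_reduction(rng, noise=0.0)
        fit = fit_unrobust(red)
        q, df, pv = heterogeneity_test(fit)
        assert q == pytest.approx(0.0, abs=1e-8)
        assert pv == pytest.approx(1.0, abs=1e-6)

    def test_statistic_at_df_matches_chi2_tables(self):
        # chi2 upper tail at q = df = 10 is about 0.44
        assert stats.chi2.sf(10, 10) == pytest.approx(0.4405, abs=5e-4)

    def test_rejects_robust_fit(self, rng):
        red, _ = random_reduction(rng, p=10, k=2, noise=0.6)
        fr = fit_robust(red)
        with pytest.raises(ValidationError):
            heterogeneity_test(fr)


class TestWaldCI:
    def test_published_style_interval(self):
        # estimate 1.146 with z*se = 0.854 gives the interval (0.292, 2.000)
        se = 0.854 / stats.norm.ppf(0.975)
        red = make_reduction(np.ones((3, 1)), np.ones(3))
        fit = fit_unrobust(red)
        fit.theta = np.array([1.146])
        fit.se_theta = np.array([se])
        ci = wald_ci(fit, 0.95)
        assert ci[0, 0] == pytest.approx(0.292, abs=5e-4)
        assert ci[0, 1] == pytest.approx(2.000, abs=5e-4)

    def test_zero_se_degenerate(self):
        red = make_reduction(np.ones((3, 1)), np.ones(3))
        fit = fit_unrobust(red)
        fit.theta, fit.se_theta = np.array([0.5]), np.array([0.0])
        ci = wald_ci(fit, 0.95)
        np.testing.assert_array_equal(ci, [[0.5, 0.5]])

    def test_nested_in_level(self, rng):
        red, _ = random_reduction(rng, noise=0.2)
        fit = fit_unrobust(red)
        ci90, ci95 = wald_ci(fit, 0.90), wald_ci(fit, 0.95)
        assert np.all(ci90[:, 0] >= ci95[:, 0]) and np.all(ci90[:, 1] <= ci95[:, 1])

    def test_invalid_level(self, rng):
        red, _ = random_reduction(rng)
        fit = fit_unrobust(red)
        with pytest.raises(ValidationError):
            wald_ci(fit, 1.5)
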
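import numpy as np
import pytest
from scipy import integrate

from cortexdensity import (
    NeurogenesisParams,
    f_inverse,
    neuron_moments,
    progenitor_moments,
    shapiro_wilk,
    sigma_N2_of_t,
    simulate_neuron_density,
    simulate_progenitors,
    t_of_y,
    y_of_t,
)
from cortexdensity.neurogenesis import _neuron_raw_moments


class TestParams:
    def test_defaults_are_calibrated_values(self, params):
        assert params.lambda_P == pytest.approx(np.log(2) / 1.5)
        assert params.sigma == 0.061
        assert params.rho0 == 3.8e3
        assert params.dt == 0.05

    @pytest.mark.parametrize("field, value", [
        ("lambda_P", -0.1), ("sigma", -0.01), ("rho0", 0.0), ("dt", 0.0),
    ])
    def test_invalid_parameters_rejected(self, params, field, value):
        with pytest.raises(ValueError):
            params.with_(**{field: value})


class TestProgenitorMoments:
    def test_initial_condition(self, params):
        m = progenitor_moments(params, 0.0)
        assert m.mu == pytest.approx(np.log(params.rho0))
        assert m.sigma2 == 0.0
        assert m.mean == pytest.approx(params.rho0)

    def test_deterministic_growth_limit(self):
        p = NeurogenesisParams(lambda_P=0.2, lambda_N=0.1, sigma=0.0, rho0=100.0)
        m = progenitor_moments(p, 10.0)
        assert m.mean == pytest.approx(100.0 * np.e, rel=1e-12)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            progenitor_moments(params, -1.0)

    def test_mean_matches_simulation(self, params):
        n = 100_000
        fin = simulate_progenitors(params, 45.0, n, seed=7, full=False)
        m = progenitor_moments(params, 45.0)
        se = fin.std(ddof=1) / np.sqrt(n)
        assert abs(fin.mean() - m.mean) < 3 * se

    def test_log_moments_match_simulation(self, params):
        n = 100_000
        logs = np.log(simulate_progenitors(params, 45.0, n, seed=8, full=False))
        m = progenitor_moments(params, 45.0)
        assert abs(logs.mean() - m.mu) < 3 * logs.std(ddof=1) / np.sqrt(n)
        var = logs.var(ddof=1)
        se_var = var * np.sqrt(2.0 / (n - 1))
        assert abs(var - m.sigma2) < 3 * se_var


class TestSimulateProgenitors:
    def test_noiseless_paths_are_exact_exponentials(self):
        p = NeurogenesisParams(lambda_P=0.3, lambda_N=0.1, sigma=0.0, rho0=50.0, dt=0.5)
        times, paths = simulate_progenitors(p, 5.0, 4, seed=0)
        expected = 50.0 * np.exp(0.2 * times)
        np.testing.assert_allclose(paths, np.tile(expected, (4, 1)), rtol=1e-12)

    def test_paths_strictly_positive_and_reproducible(self, params):
        _, a = simulate_progenitors(params, 10.0, 100, seed=42)
        _, b = simulate_progenitors(params, 10.0, 100, seed=42)
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)

    def test_log_density_is_gaussian(self, params):
        # the log-domain stepping makes ln(rho_P) exactly Gaussian, so the
        # SW test should behave at its nominal level
        ok = 0
        for seed in range(20):
            fin = simulate_progenitors(params, 45.0, 4000, seed=seed, full=False)
            ok += shapiro_wilk(np.log(fin))[1] > 0.05
        assert ok >= 18

    def test_ito_mode_differs_in_mean(self, params):
        # Ito Euler-Maruyama mean stays at rho0 (zero drift), missing the
        # exp(sigma^2 t / 2) Stratonovich factor
        n = 50_000
        fin = simulate_progenitors(params, 45.0, n, seed=3, full=False, mode="ito")
        se = fin.std(ddof=1) / np.sqrt(n)
        assert abs(fin.mean() - params.rho0) < 3 * se


class TestSimulateNeuronDensity:
    def test_zero_neurogenesis_rate(self, params):
        p = params.with_(lambda_N=0.0, lambda_P=0.0)
        rho = simulate_neuron_density(p, 10.0, 10, seed=0)
        np.testing.assert_array_equal(rho, 0.0)

    def test_noiseless_linear_accumulation(self):
        lam = 0.4
        p = NeurogenesisParams(lambda_P=lam, lambda_N=lam, sigma=0.0, rho0=100.0, dt=0.05)
        rho = simulate_neuron_density(p, 10.0, 3, seed=0)
        np.testing.assert_allclose(rho, lam * 100.0 * 10.0, rtol=2 * p.dt)

    def test_mean_matches_closed_form(self, params):
        n = 100_000
        rho = simulate_neuron_density(params, 45.0, n, seed=3)
        lam, s2 = params.lambda_N, params.sigma**2
        closed = params.rho0 * (2 * lam / s2) * np.expm1(s2 * 45.0 / 2)
        se = rho.std(ddof=1) / np.sqrt(n)
        assert abs(rho.mean() - closed) < 3 * se

    def test_discretization_control(self, params):
        # halving dt leaves the t=45 mean within Monte-Carlo resolution
        n = 60_000
        a = simulate_neuron_density(params, 45.0, n, seed=11)
        b = simulate_neuron_density(params.with_(dt=0.025), 45.0, n, seed=12)
        se = np.sqrt(a.var(ddof=1) / n + b.var(ddof=1) / n)
        assert abs(a.mean() - b.mean()) < 3 * se


class TestNeuronMoments:
    def test_variance_vanishes_at_short_times(self, params):
        # sigma_N^2 ~ (2/3)(sigma^2/2) t as t -> 0+
        assert sigma_N2_of_t(params, 1e-9) < 1e-11
        assert sigma_N2_of_t(params, 1e-12) < 1e-14

    def test_zero_time_rejected(self, params):
        with pytest.raises(ValueError):
            neuron_moments(params, 0.0)

    def test_second_moment_against_quadrature(self, params):
        # 2-D quadrature of the covariance integral over the exact
        # progenitor moments
        lam = params.lambda_N
        a = 0.5 * params.sigma**2

        def cov(s, sp):
            return np.exp(a * s + a * sp + 2 * a * np.minimum(s, sp))

        t = 45.0
        val, _ = integrate.dblquad(
            lambda s, sp: lam**2 * params.rho0**2 * cov(s, sp),
            0, t, 0, t, epsabs=1e-10, epsrel=1e-10,
        )
        _, m2 = _neuron_raw_moments(params, t)
        assert m2 == pytest.approx(val, rel=1e-8)

    def test_mean_against_quadrature(self, params):
        t = 45.0
        a = 0.5 * params.sigma**2
        val, _ = integrate.quad(
            lambda s: params.lambda_N * params.rho0 * np.exp(a * s), 0, t,
            epsabs=1e-12, epsrel=1e-12,
        )
        assert neuron_moments(params, t).mean == pytest.approx(val, rel=1e-10)

    def test_sigma_N2_strictly_increasing(self, params):
        grid = np.linspace(0.5, 120.0, 240)
        vals = np.array([sigma_N2_of_t(params, t) for t in grid])
        assert np.all(np.diff(vals) > 0)

    def test_general_rates_reduce_to_equal_rate_form(self, params):
        # the general constant-rate branch agrees with the stable
        # equal-rate branch when rates coincide numerically
        p_gen = params.with_(lambda_P=params.lambda_N + 1e-13)
        m_eq = neuron_moments(params, 45.0)
        m_gen = neuron_moments(p_gen, 45.0)
        assert m_gen.mean == pytest.approx(m_eq.mean, rel=1e-6)
        assert m_gen.sigma2 == pytest.approx(m_eq.sigma2, rel=1e-4)


class TestAuxiliaryMap:
    def test_calibrated_value_at_median_time(self, params):
        assert y_of_t(params, 45.0) == pytest.approx(3.07, abs=0.01)

    def test_small_time_lognormal_limit(self, params):
        t = 1e-6
        assert y_of_t(params, t) == pytest.approx(np.log(params.lambda_N * t), rel=1e-4)

    @pytest.mark.parametrize("t", [30.0, 60.0])
    def test_matches_quadrature_of_general_definition(self, params, t):
        a = 0.5 * params.sigma**2
        val, _ = integrate.quad(lambda s: params.lambda_N * np.exp(a * s), 0, t,
                                epsabs=1e-13, epsrel=1e-13)
        assert y_of_t(params, t) == pytest.approx(np.log(val), abs=1e-10)

    def test_nonpositive_time_rejected(self, params):
        with pytest.raises(ValueError):
            y_of_t(params, 0.0)

    @pytest.mark.parametrize("t", [1.0, 30.0, 45.0, 60.0, 120.0])
    def test_t_of_y_round_trip(self, params, t):
        assert t_of_y(params, y_of_t(params, t)) == pytest.approx(t, abs=1e-10)

    def test_inverse_value_at_calibrated_mean(self, params):
        assert t_of_y(params, 3.07) == pytest.approx(45.0, abs=0.5)

    def test_t_vanishes_monotonically_as_y_decreases(self, params):
        ys = np.linspace(-30, 3, 100)
        ts = t_of_y(params, ys)
        assert np.all(np.diff(ts) > 0)
        assert ts[0] < 1e-10

    def test_large_time_gaussian_asymptote(self, params):
        # gap y(t) - [ln(2 lambda/sigma^2) + sigma^2 t/2] = ln(1 - e^{-sigma^2 t/2})
        s2 = params.sigma**2
        gaps = [abs(y_of_t(params, t) - (np.log(2 * params.lambda_N / s2) + 0.5 * s2 * t))
                for t in (1000.0, 2000.0, 5000.0, 10000.0)]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-6


class TestFInverse:
    def test_composition_identity(self, params):
        # f(f^-1(x)) = x where f maps y -> sigma_N^2 through t(y)
        for x in (0.05, 0.1, 0.2):
            y = f_inverse(params, x)
            t = t_of_y(params, y)
            assert sigma_N2_of_t(params, t) == pytest.approx(x, abs=1e-8)

    def test_consistency_with_y_of_t(self, params):
        v = sigma_N2_of_t(params, 45.0)
        assert f_inverse(params, v) == pytest.approx(y_of_t(params, 45.0), abs=1e-10)

    def test_boundary_rejected(self, params):
        with pytest.raises(ValueError):
            f_inverse(params, 0.0)

    def test_strictly_increasing(self, params):
        v = np.linspace(1e-4, 0.5, 200)
        out = f_inverse(params, v)
        assert np.all(np.diff(out) > 0)
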
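"""Exact-kernel, continuum and Gaussian-approximation checks.

The independent oracle throughout is the chemical-master-equation generator
propagated by matrix exponential (and, for the continuum model, direct ODE
integration); the analytic convolved-binomial kernel must agree with it.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.stats import binom

from cntsense import (
    SensorParams,
    cme_generator,
    cme_propagate,
    continuum_update,
    count_loglik,
    gaussian_obs_moments,
    occupancy_fractions,
    stationary_dist,
    transition_pmf,
)
from cntsense.sensor_model import occupancy_fraction_derivatives

K = np.arange(11)  # occupancy support for NT=10


class TestSensorParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kA=-1.0, kD=0.001, NT=10, dt=1.0),
            dict(kA=100.0, kD=-0.1, NT=10, dt=1.0),
            dict(kA=100.0, kD=0.001, NT=0, dt=1.0),
            dict(kA=100.0, kD=0.001, NT=10, dt=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SensorParams(**kwargs)


class TestOccupancyFractions:
    def test_no_desorption_occupied_sites_never_empty(self):
        p = SensorParams(kA=100.0, kD=0.0, NT=10, dt=1.0)
        lam = occupancy_fractions(p, 1e-5)
        assert lam.lamF == 1.0
        assert lam.lamE == pytest.approx(1.0 - math.exp(-1e-3), rel=1e-12)

    def test_zero_interval_is_identity(self, params):
        p = SensorParams(kA=params.kA, kD=params.kD, NT=params.NT, dt=1e-12)
        lam = occupancy_fractions(p, 1e-5)
        assert lam.lamF == pytest.approx(1.0, abs=1e-11)
        assert lam.lamE == pytest.approx(0.0, abs=1e-11)

    def test_reference_values(self, params):
        # direct evaluation with a = kA*C + kD = 2e-3
        lam = occupancy_fractions(params, 1e-5)
        assert lam.lamF == pytest.approx(0.9990009993336666, rel=1e-12)
        assert lam.lamE == pytest.approx(9.990006663334605e-4, rel=1e-12)

    def test_pure_desorption_limit_at_zero_concentration(self, params):
        lam = occupancy_fractions(params, 0.0)
        assert lam.lamE == 0.0
        assert lam.lamF == pytest.approx(math.exp(-params.kD * params.dt),
                                         rel=1e-14)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            occupancy_fractions(params, -1e-9)

    @given(
        kA=st.floats(1.0, 1e4),
        kD=st.floats(0.0, 1.0),
        dt=st.floats(1e-3, 10.0),
        C=st.floats(0.0, 1e-3),
    )
    def test_bounds_and_difference_identity(self, kA, kD, dt, C):
        p = SensorParams(kA=kA, kD=kD, NT=10, dt=dt)
        lam = occupancy_fractions(p, C)
        assert 0.0 <= lam.lamE <= lam.lamF <= 1.0
        assert lam.lamF - lam.lamE == pytest.approx(
            math.exp(-(kA * C + kD) * dt), rel=1e-10, abs=1e-12
        )

    def test_fill_probability_increasing_in_concentration(self, params):
        C = np.linspace(0, 1e-4, 50)
        lamE = np.array([occupancy_fractions(params, c).lamE for c in C])
        assert np.all(np.diff(lamE) > 0)


class TestContinuumUpdate:
    def test_steady_state_is_fixed_point(self, params):
        for C in (1e-6, 1e-5, 1e-4):
            Nss = params.NT * params.kA * C / (params.kA * C + params.kD)
            assert continuum_update(params, Nss, C) == pytest.approx(
                Nss, rel=1e-12
            )

    def test_one_step_from_empty_matches_ode_oracle(self, params):
        C = 1e-5
        # oracle: integrate dN/dt = kA*C*(NT-N) - kD*N over one interval
        sol = solve_ivp(
            lambda t, N: params.kA * C * (params.NT - N) - params.kD * N,
            (0.0, params.dt), [0.0], rtol=1e-12, atol=1e-14,
        )
        expected = sol.y[0, -1]
        assert continuum_update(params, 0.0, C) == pytest.approx(
            expected, rel=1e-9
        )
        assert continuum_update(params, 0.0, C) == pytest.approx(
            0.009990006663, rel=1e-9
        )

    @given(N_prev=st.floats(0.0, 10.0), C=st.floats(0.0, 1e-3))
    def test_equals_lambda_mixture_identity(self, params, N_prev, C):
        lam = occupancy_fractions(params, C)
        expected = N_prev * lam.lamF + (params.NT - N_prev) * lam.lamE
        assert continuum_update(params, N_prev, C) == pytest.approx(
            expected, rel=1e-12, abs=1e-15
        )

    def test_out_of_range_previous_count_rejected(self, params):
        with pytest.raises(ValueError):
            continuum_update(params, -0.1, 1e-5)
        with pytest.raises(ValueError):
            continuum_update(params, 10.1, 1e-5)


class TestTransitionPmf:
    def test_normalized_over_grid(self, params, conc_grid):
        for C in conc_grid:
            for y_prev in range(params.NT + 1):
                pmf = transition_pmf(params, y_prev, C)
                assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(pmf >= 0)

    def test_from_empty_reduces_to_single_binomial(self, params):
        C = 1e-5
        lamE = occupancy_fractions(params, C).lamE
        pmf = transition_pmf(params, 0, C)
        assert pmf == pytest.approx(binom.pmf(K, params.NT, lamE), abs=1e-14)
        # single-binomial form with lambda = continuum mean / NT
        lam = continuum_update(params, 0.0, C) / params.NT
        assert lam == pytest.approx(lamE, rel=1e-12)

    def test_agrees_with_cme_matrix_exponential(self, params, conc_grid):
        for C in conc_grid:
            for y_prev in range(params.NT + 1):
                init = np.zeros(params.NT + 1)
                init[y_prev] = 1.0
                oracle = cme_propagate(params, init, C, params.dt)
                tv = 0.5 * np.abs(
                    transition_pmf(params, y_prev, C) - oracle
                ).sum()
                assert tv <= 1e-8

    def test_reference_probability_of_staying_empty(self, params):
        # (1 - lamE)**10 with lamE ~ 9.99e-4
        assert transition_pmf(params, 0, 1e-5)[0] == pytest.approx(
            0.9900547840098874, rel=1e-10
        )

    def test_zero_interval_is_point_mass(self, params):
        p = SensorParams(params.kA, params.kD, params.NT, dt=1e-12)
        for y_prev in (0, 4, 10):
            pmf = transition_pmf(p, y_prev, 1e-5)
            assert pmf[y_prev] == pytest.approx(1.0, abs=1e-10)

    def test_mean_equals_continuum_update(self, params, conc_grid):
        for C in conc_grid:
            for y_prev in range(params.NT + 1):
                mean = transition_pmf(params, y_prev, C) @ K
                assert mean == pytest.approx(
                    continuum_update(params, float(y_prev), C), abs=1e-10
                )

    @pytest.mark.parametrize("bad", [-1, 11, 2.5])
    def test_invalid_previous_count_rejected(self, params, bad):
        with pytest.raises(ValueError):
            transition_pmf(params, bad, 1e-5)


class TestCmePropagate:
    def test_zero_duration_identity(self, params):
        init = stationary_dist(params, 3e-6)
        assert cme_propagate(params, init, 3e-6, 0.0) == pytest.approx(init)

    def test_long_run_reaches_binomial_stationary_law(self, params):
        # kA*C/(kA*C+kD) = 0.5 at C = 10 uM
        init = np.zeros(11)
        init[0] = 1.0
        out = cme_propagate(params, init, 1e-5, 1e5)
        assert out == pytest.approx(binom.pmf(K, 10, 0.5), abs=1e-9)
        assert out @ K == pytest.approx(5.0, abs=1e-8)

    def test_stationary_dist_is_generator_null_vector(self, params):
        pi = stationary_dist(params, 1e-5)
        G = cme_generator(params, 1e-5)
        assert G @ pi == pytest.approx(np.zeros(11), abs=1e-15)

    def test_unnormalized_input_rejected(self, params):
        with pytest.raises(ValueError):
            cme_propagate(params, np.full(11, 0.2), 1e-5, 1.0)


class TestGaussianMoments:
    def test_nothing_to_adsorb_or_desorb(self, params):
        m = gaussian_obs_moments(params, 0, 0.0)
        assert m.mean == 0.0 and m.var == 0.0

    def test_moments_match_exact_kernel(self, params, conc_grid):
        for C in conc_grid:
            for y_prev in range(params.NT + 1):
                pmf = transition_pmf(params, y_prev, C)
                mean, var = pmf @ K, pmf @ K**2 - (pmf @ K) ** 2
                m = gaussian_obs_moments(params, y_prev, C)
                assert m.mean == pytest.approx(mean, abs=1e-10)
                assert m.var == pytest.approx(var, abs=1e-10)

    def test_jacobian_matches_finite_differences(self, params):
        for C in (1e-7, 1e-6, 1e-5, 1e-4):
            eps = 1e-3 * C
            dF, dE = occupancy_fraction_derivatives(params, np.asarray(C))
            fp = occupancy_fractions(params, C + eps)
            fm = occupancy_fractions(params, C - eps)
            assert dF == pytest.approx((fp.lamF - fm.lamF) / (2 * eps),
                                       rel=1e-4)
            assert dE == pytest.approx((fp.lamE - fm.lamE) / (2 * eps),
                                       rel=1e-6)


class TestCountLoglik:
    def test_exact_mode_normalizes(self, params):
        for y_prev in (0, 5, 10):
            total = sum(
                math.exp(count_loglik(params, y, y_prev, 1e-5))
                for y in range(11)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_mode_close_but_not_exact(self, params):
        # discretized-normal vs exact pmf: bounded, nonzero divergence
        exact = transition_pmf(params, 5, 1e-5)
        gauss = np.array([
            math.exp(count_loglik(params, y, 5, 1e-5, mode="gaussian"))
            for y in range(11)
        ])
        gauss /= gauss.sum()
        tv = 0.5 * np.abs(exact - gauss).sum()
        assert 0.0 < tv < 0.5

    def test_degenerate_gaussian_variance(self, params):
        # C = 0, empty sensor: next count is deterministically 0
        assert count_loglik(params, 1, 0, 0.0, mode="gaussian") == -np.inf
        capped = count_loglik(params, 0, 0, 0.0, mode="gaussian")
        assert np.isfinite(capped) and capped > 0

    def test_unknown_mode_rejected(self, params):
        with pytest.raises(ValueError):
            count_loglik(params, 0, 0, 1e-5, mode="laplace")
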
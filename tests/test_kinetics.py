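"""Sequential N->I->U kinetics: closed forms, ODE oracle, trace fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import phasorfold as pf
from phasorfold.aggregation_kinetics import KineticParams
from phasorfold.exceptions import (
    ConfigError,
    DomainError,
    UndefinedLagError,
    ValidationError,
)


def ode_oracle(k1, k2, times, n0=1.0):
    """Numerical integration of dN/dt=-k1 N, dI/dt=k1 N - k2 I, dU/dt=k2 I."""
    sol = solve_ivp(
        lambda t, y: [-k1 * y[0], k1 * y[0] - k2 * y[1], k2 * y[1]],
        (0.0, float(times[-1]) if times[-1] > 0 else 1.0),
        [n0, 0.0, 0.0],
        t_eval=times,
        rtol=1e-11,
        atol=1e-13,
        method="LSODA",
    )
    return sol.y


class TestSpeciesProfiles:
    def test_initial_condition(self):
        p = KineticParams(0.3, 1.2, N0=2.5)
        n, i, u = pf.species_profiles(p, [0.0])
        assert (n[0], i[0], u[0]) == pytest.approx((2.5, 0.0, 0.0), abs=1e-14)

    def test_mass_conservation(self):
        p = KineticParams(0.25, 2.22)
        t = np.linspace(0.0, 50.0, 200)
        n, i, u = pf.species_profiles(p, t)
        np.testing.assert_allclose(n + i + u, 1.0, atol=1e-12)
        assert (n >= 0).all() and (i >= 0).all() and (u >= 0).all()

    def test_profiles_match_ode_oracle(self):
        p = KineticParams(0.25, 2.22)
        t = np.array([1.0, 5.0, 10.0])
        closed = np.vstack(pf.species_profiles(p, t))
        np.testing.assert_allclose(closed, ode_oracle(0.25, 2.22, t), atol=1e-8)

    def test_intermediate_peak_time(self):
        p = KineticParams(0.25, 2.22)
        t_star = pf.intermediate_peak_time(p)
        assert t_star == pytest.approx(np.log(0.25 / 2.22) / (0.25 - 2.22), rel=1e-12)
        eps = 1e-4
        _, i0, _ = pf.species_profiles(p, [t_star - eps, t_star, t_star + eps])
        assert i0[1] >= i0[0] and i0[1] >= i0[2]

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            pf.species_profiles(KineticParams(1.0, 2.0), [-1.0])

    @given(
        logk1=st.floats(-2.0, 1.0),
        logk2=st.floats(-2.0, 1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_closed_form_equals_ode_everywhere(self, logk1, logk2):
        k1, k2 = 10.0**logk1, 10.0**logk2
        t = np.linspace(0.0, 10.0 / min(k1, k2), 40)
        closed = np.vstack(pf.species_profiles(KineticParams(k1, k2), t))
        np.testing.assert_allclose(closed, ode_oracle(k1, k2, t), atol=1e-8)


class TestModelF:
    def test_f0_equals_a(self):
        p = KineticParams(0.7, 0.2, k3_per_min=0.3, m_au=100.0, a_au=12.5)
        assert pf.model_F(p, [0.0])[0] == pytest.approx(12.5, abs=1e-12)

    def test_rate_swap_symmetry(self):
        t = np.linspace(0.0, 40.0, 101)
        fa = pf.model_F(KineticParams(0.25, 2.22, 0.01, 50.0, 3.0), t)
        fb = pf.model_F(KineticParams(2.22, 0.25, 0.01, 50.0, 3.0), t)
        np.testing.assert_allclose(fa, fb, rtol=1e-12, atol=1e-12)

    def test_asymptote_without_drift(self):
        p = KineticParams(0.25, 2.22, 0.0, m_au=7.0, a_au=1.0)
        assert pf.model_F(p, [1e4])[0] == pytest.approx(8.0, rel=1e-10)

    def test_reference_value_against_ode(self):
        # k1=0.25, k2=2.22, m=1, a=0, k3=0 at t=10 min
        val = pf.model_F(KineticParams(0.25, 2.22, 0.0, 1.0, 0.0), [10.0])[0]
        assert val == pytest.approx(0.9075, abs=1e-4)
        u_ode = ode_oracle(0.25, 2.22, np.array([10.0]))[2, 0]
        assert val == pytest.approx(u_ode, abs=1e-8)

    def test_continuity_at_equal_rates(self):
        t = np.linspace(0.0, 30.0, 50)
        k = 0.4
        f_branch = pf.model_F(KineticParams(k, k, 0.0, 1.0, 0.0), t)
        f_near = pf.model_F(KineticParams(k * (1 + 5e-8), k, 0.0, 1.0, 0.0), t)
        np.testing.assert_allclose(f_branch, f_near, atol=1e-6)

    def test_monotone_for_nonnegative_drift(self):
        t = np.linspace(0.0, 60.0, 300)
        f = pf.model_F(KineticParams(0.5, 0.05, 0.02, 10.0, 1.0), t)
        assert (np.diff(f) >= -1e-12).all()


class TestFitTrace:
    def test_noiseless_recovery(self):
        t = np.linspace(0.0, 100.0, 200)
        truth = dict(k1_per_min=0.50, k2_per_min=0.05, m_au=200.0, a_au=10.0)
        cfg = pf.KineticConfig(times_min=t, noise_sd_au=0.0, seed=1, **truth)
        fit = pf.fit_trace(pf.simulate_tht_trace(cfg))
        assert fit.converged
        assert fit.params.k1_per_min == pytest.approx(0.50, rel=1e-3)
        assert fit.params.k2_per_min == pytest.approx(0.05, rel=1e-3)
        assert fit.params.m_au == pytest.approx(200.0, rel=1e-3)
        assert fit.params.a_au == pytest.approx(10.0, rel=1e-3)
        assert abs(fit.params.k3_per_min) < 1e-4
        assert fit.r_squared > 0.999999

    def test_canonical_ordering(self):
        t = np.linspace(0.0, 30.0, 120)
        cfg = pf.KineticConfig(
            k1_per_min=0.25, k2_per_min=2.22, times_min=t, m_au=100.0, seed=2
        )
        fit = pf.fit_trace(pf.simulate_tht_trace(cfg))
        assert fit.params.k1_per_min >= fit.params.k2_per_min
        assert fit.params.k1_per_min == pytest.approx(2.22, rel=1e-3)
        assert fit.params.k2_per_min == pytest.approx(0.25, rel=1e-3)

    def test_noisy_recovery_single_seed(self):
        t = np.concatenate(
            [np.linspace(0, 10, 100, endpoint=False), np.linspace(10, 100, 100)]
        )
        cfg = pf.KineticConfig(
            k1_per_min=0.5, k2_per_min=0.05, times_min=t,
            m_au=200.0, a_au=10.0, noise_sd_au=2.0, seed=7,
        )
        fit = pf.fit_trace(pf.simulate_tht_trace(cfg), fix_k3=True)
        assert fit.params.k1_per_min == pytest.approx(0.5, rel=0.1)
        assert fit.params.k2_per_min == pytest.approx(0.05, rel=0.05)

    def test_flat_trace_rejected(self):
        trace = pf.KineticTrace(np.linspace(0, 10, 20), np.full(20, 3.0))
        with pytest.raises(ValidationError):
            pf.fit_trace(trace)

    def test_too_few_points(self):
        trace = pf.KineticTrace([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(Exception):
            pf.fit_trace(trace)


class TestLagPhase:
    def _fit(self, k1, k2):
        return pf.KineticFit(
            params=KineticParams(k1, k2, 0.0, 100.0, 0.0),
            stderr={}, r_squared=1.0, converged=True,
        )

    def test_fast_rates_no_lag(self):
        flag, t_lag = pf.lag_phase_flag(self._fit(2.0, 1.0))
        assert not flag
        assert t_lag < 1.0

    def test_slow_equal_rates_long_lag(self):
        flag, t_lag = pf.lag_phase_flag(self._fit(0.01, 0.01))
        assert flag
        assert t_lag > 30.0

    def test_lag_time_is_exact_root(self):
        fit = self._fit(0.5, 0.05)
        _, t_lag = pf.lag_phase_flag(fit, fraction=0.05)
        u = pf.model_F(KineticParams(0.5, 0.05, 0.0, 1.0, 0.0), [t_lag])[0]
        assert u == pytest.approx(0.05, abs=1e-8)

    def test_zero_amplitude_undefined(self):
        fit = pf.KineticFit(
            params=KineticParams(1.0, 0.5, 0.0, 0.0, 0.0),
            stderr={}, r_squared=1.0, converged=True,
        )
        with pytest.raises(UndefinedLagError):
            pf.lag_phase_flag(fit)


class TestConfigValidation:
    @pytest.mark.parametrize("k1,k2", [(0.0, 1.0), (1.0, -0.1)])
    def test_nonpositive_rates_rejected(self, k1, k2):
        with pytest.raises(ConfigError):
            pf.KineticConfig(k1_per_min=k1, k2_per_min=k2,
                             times_min=np.arange(5.0), seed=1)

    def test_seed_mandatory(self):
        with pytest.raises(ConfigError):
            pf.KineticConfig(k1_per_min=1.0, k2_per_min=0.5, times_min=np.arange(5.0))
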
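"""Forward simulator: steady state, sweeps, stiffening, physical sanity."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from derheo.io import ValidationError
from derheo.simulate import (LumpedSystem, default_system,
                             simulate_calibration_sweep, simulate_sweeps,
                             steady_state_response, stiffening_series,
                             make_cell_system)


class TestSteadyState:
    def test_static_limit_force_balance_on_slave(self):
        kc = 3e-3
        sys = default_system(kc)
        Xm, Xs = steady_state_response(sys, "master", np.array([0.5, 1.0]))
        ratio = (Xs.values / Xm.values)[0]
        assert ratio.real == pytest.approx(kc / (sys.k_s + kc), rel=1e-5)
        assert abs(ratio.imag) < 1e-3 * ratio.real

    def test_zero_coupling_decouples(self, f_grid):
        sys = default_system(0.0)
        _, Xs = steady_state_response(sys, "master", f_grid)
        np.testing.assert_array_equal(Xs.values, 0.0)

    def test_reciprocity_under_symmetric_forces(self, f_grid):
        sys = default_system(3e-3 + 5e-4j)
        _, Xs = steady_state_response(sys, "master", f_grid)
        Xm, _ = steady_state_response(sys, "slave", f_grid)
        np.testing.assert_allclose(Xs.values, Xm.values, rtol=1e-12)

    def test_energy_balance_with_real_cell_spring(self):
        # with k_c real the cell stores but never dissipates: the injected
        # power must equal the dashpot dissipation
        sys = default_system(3e-3)
        for f in (2e3, 9e3, 25e3):
            w = 2 * math.pi * f
            Xm, Xs = steady_state_response(sys, "master", np.array([f]))
            xm, xs = Xm.values[0], Xs.values[0]
            p_in = 0.5 * np.real(sys.F_m * np.conj(1j * w * xm))
            p_diss = 0.5 * w**2 * (sys.c_m * abs(xm) ** 2
                                   + sys.c_s * abs(xs) ** 2)
            assert p_in == pytest.approx(p_diss, rel=1e-9)

    def test_frequency_domain_agrees_with_time_domain_ode(self):
        # the harmonic solver against direct integration of the equations of
        # motion, steady state after transient decay, at 5 probe frequencies
        sys = default_system(3e-3)
        kc = 3e-3
        tau = 2 * sys.m_m / sys.c_m  # amplitude decay time

        def run(f):
            w = 2 * math.pi * f

            def rhs(t, y):
                xm, vm, xs, vs = y
                F = sys.F_m * math.cos(w * t)
                am = (F - sys.k_m * xm - sys.c_m * vm
                      + kc * (xs - xm)) / sys.m_m
                a_s = (-sys.k_s * xs - sys.c_s * vs
                       + kc * (xm - xs)) / sys.m_s
                return [vm, am, vs, a_s]

            t_settle = math.ceil(16 * tau * f) / f  # integer cycles
            t_meas = np.linspace(t_settle, t_settle + 6 / f, 1500)
            sol = solve_ivp(rhs, (0, t_meas[-1]), [0, 0, 0, 0],
                            t_eval=t_meas, rtol=1e-10, atol=1e-16,
                            max_step=1 / (40 * f))
            ref = np.exp(-1j * w * sol.t)
            span = t_meas[-1] - t_meas[0]
            Xm = 2 * np.trapezoid(sol.y[0] * ref, sol.t) / span
            Xs = 2 * np.trapezoid(sol.y[2] * ref, sol.t) / span
            return Xm, Xs

        for f in (2e3, 5e3, 9e3, 15e3, 30e3):
            Xm_fd, Xs_fd = steady_state_response(sys, "master",
                                                 np.array([f]))
            Xm_td, Xs_td = run(f)
            assert abs(Xm_td - Xm_fd.values[0]) / abs(Xm_fd.values[0]) < 1e-3
            assert abs(Xs_td - Xs_fd.values[0]) / abs(Xs_fd.values[0]) < 1e-3


class TestSimulateSweeps:
    def test_fixed_seed_bit_identical(self, f_grid):
        sys = default_system(3e-3)
        kw = dict(noise={"amplitude_sigma": 0.01, "phase_sigma": 0.005},
                  background=(5e-5, 0.3), seed=123)
        a = simulate_sweeps(sys, f_grid, **kw)
        b = simulate_sweeps(sys, f_grid, **kw)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.amplitudes, s2.amplitudes)
            np.testing.assert_array_equal(s1.phases, s2.phases)

    def test_background_injection_per_chain(self, f_grid):
        sys = default_system(3e-3)
        bg = {"master": (5e-5, 0.3), "slave": (3e-5, -0.2)}
        clean = simulate_sweeps(sys, f_grid)
        dirty = simulate_sweeps(sys, f_grid, background=bg)
        np.testing.assert_allclose(
            dirty[0].phases - clean[0].phases, 5e-5 * f_grid + 0.3,
            atol=1e-12)
        np.testing.assert_allclose(
            dirty[2].phases - clean[2].phases, 3e-5 * f_grid - 0.2,
            atol=1e-12)

    def test_calibration_sweep_is_cantilever_alone(self, f_grid):
        sys = default_system(3e-3)
        cal = simulate_calibration_sweep(sys, "master", f_grid)
        expected = np.abs(sys.g_m(f_grid)) * sys.F_m
        np.testing.assert_allclose(cal.amplitudes, expected, rtol=1e-12)


class TestStiffening:
    def test_multiplier_one_is_baseline(self, f_grid):
        sys = default_system(3e-3)
        base = simulate_sweeps(sys, f_grid)
        series = stiffening_series(sys, [1.0, 2.0], f_grid)
        for s1, s2 in zip(base, series[0]):
            np.testing.assert_array_equal(s1.amplitudes, s2.amplitudes)

    def test_monotonic_amplitude_and_phase_at_subresonance(self):
        # hardening raises the transmitted amplitude and lowers the phase lag
        f = np.array([5e3, 6e3])
        series = stiffening_series(default_system(3e-3),
                                   [1, 2, 5, 10, 30, 100], f)
        amps = [t[1].amplitudes[0] for t in series]
        lags = [t[1].phases[0] for t in series]
        assert np.all(np.diff(amps) > 0)
        assert np.all(np.diff(lags) < 0)

    def test_infinite_stiffness_limit_is_rigid_link(self, f_grid):
        # k_c -> inf: the two masses move together; response of the bound
        # pair to the master drive
        sys = default_system(3e-3)
        big = stiffening_series(sys, [1e8 / 3e-3], f_grid)[0]
        w = 2 * math.pi * f_grid
        denom = (sys.k_m + sys.k_s + 1j * w * (sys.c_m + sys.c_s)
                 - w**2 * (sys.m_m + sys.m_s))
        rigid = np.abs(sys.F_m / denom)
        np.testing.assert_allclose(big[1].amplitudes, rigid, rtol=1e-4)

    def test_decreasing_multipliers_rejected(self, f_grid):
        with pytest.raises(ValidationError):
            stiffening_series(default_system(), [2.0, 1.0], f_grid)


class TestMakeCellSystem:
    def test_elastic_cell_gives_real_constant_stiffness(self, f_grid, cell,
                                                        cantilever):
        sys = make_cell_system(cantilever, cantilever, cell,
                               ("double_pl", {"A": 1000.0, "B": 0.0,
                                              "alpha": 0.0, "beta": 0.0}))
        kc = sys.kc(f_grid)
        np.testing.assert_allclose(kc.imag, 0.0, atol=1e-20)
        assert np.ptp(kc.real) == pytest.approx(0.0, abs=1e-15)

    def test_double_pl_cell_phase_increases(self, f_grid, cell, cantilever):
        sys = make_cell_system(cantilever, cantilever, cell,
                               ("double_pl", {"A": 1000.0, "B": 50.0,
                                              "alpha": 0.1, "beta": 0.9}))
        phase = np.angle(sys.kc(f_grid))
        assert np.all(np.diff(phase) > 0)
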
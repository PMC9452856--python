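import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coreshell as cs
from coreshell.parameters import GroupParameters, nondimensionalize
from coreshell.reduced_model import (
    classify_eigenvalues,
    free_running_state,
    macro_jacobian,
    macro_rhs,
)


def isolated_core_params(K_vv=5.6):
    """No intercoupling, no cue: the core evolves as a single forced-free group."""
    return nondimensionalize(
        GroupParameters(tau=25.1, sigma=1.3), GroupParameters(tau=23.3, sigma=1.9),
        K_vv=K_vv, K_dd=4.0, K_vd=0.0, K_dv=0.0, F=0.0,
    )


class TestMacroRhs:
    def test_fully_coherent_core_decays_at_spread_rate(self):
        """At rho_v = 1 every (1 - rho^2) term vanishes: drho_v/dt = -delta_v."""
        p = isolated_core_params()
        d = cs.DriveSpec(mode="DD")
        for psi_v, psi_d in [(0.0, 0.0), (1.2, -0.7), (-2.0, 0.4)]:
            f = macro_rhs([1.0, psi_v, 0.6, psi_d], p, d)
            assert f[0] == pytest.approx(-p.dimensionless.delta_v, rel=1e-12)

    def test_aligned_groups_leave_shell_phase_at_detuning(self, table1):
        """With psi_v = psi_d the shell phase equation reduces to -Omega_d."""
        drive = cs.DriveSpec(mode="LD", T=24.0)
        omega_F = table1.omega_dimensionless(drive.omega_F_h)
        f = macro_rhs([0.7, 0.3, 0.5, 0.3], table1, drive)
        assert f[3] == pytest.approx(-(omega_F - table1.dimensionless.omega_d), rel=1e-12)

    def test_decoupled_groups_are_independent(self, table1, rng):
        """With zero intercoupling, core derivatives ignore the shell state."""
        from dataclasses import replace
        p = replace(table1, K_vd=0.0, K_dv=0.0)
        drive = cs.DriveSpec(mode="LD", T=24.0)
        for _ in range(10):
            y1 = [0.7, 0.2, rng.uniform(0.1, 0.9), rng.uniform(-3, 3)]
            y2 = [0.7, 0.2, rng.uniform(0.1, 0.9), rng.uniform(-3, 3)]
            f1, f2 = macro_rhs(y1, p, drive), macro_rhs(y2, p, drive)
            assert f1[0] == f2[0] and f1[1] == f2[1]

    @given(chi=st.floats(-3.1, 3.1), rho_v=st.floats(0.1, 0.95), rho_d=st.floats(0.1, 0.95))
    def test_parity_in_phase_difference(self, chi, rho_v, rho_d, table1):
        """rho equations are even and psi equations odd in the phase difference."""
        drive = cs.DriveSpec(mode="DD")
        d = table1.dimensionless
        f_plus = macro_rhs([rho_v, 0.0, rho_d, chi], table1, drive)
        f_minus = macro_rhs([rho_v, 0.0, rho_d, -chi], table1, drive)
        assert f_plus[0] == pytest.approx(f_minus[0], rel=1e-12, abs=1e-12)
        assert f_plus[2] == pytest.approx(f_minus[2], rel=1e-12, abs=1e-12)
        # subtract the detuning part before checking oddness
        assert f_plus[1] - d.omega_v == pytest.approx(-(f_minus[1] - d.omega_v),
                                                      rel=1e-9, abs=1e-12)
        assert f_plus[3] - d.omega_d == pytest.approx(-(f_minus[3] - d.omega_d),
                                                      rel=1e-9, abs=1e-12)

    def test_rho_floor_regularizes_incoherent_phase(self, table1):
        f = macro_rhs([0.0, 0.0, 0.5, 0.2], table1, cs.DriveSpec(mode="LD", T=24.0))
        assert np.all(np.isfinite(f))


class TestJacobian:
    def test_matches_finite_differences(self, table1, rng):
        drive = cs.DriveSpec(mode="LD", T=24.7)
        h = 1e-6
        for _ in range(20):
            y = np.array([rng.uniform(0.2, 0.95), rng.uniform(-3, 3),
                          rng.uniform(0.2, 0.95), rng.uniform(-3, 3)])
            J = macro_jacobian(y, table1, drive)
            Jfd = np.empty((4, 4))
            for j in range(4):
                yp, ym = y.copy(), y.copy()
                yp[j] += h
                ym[j] -= h
                Jfd[:, j] = (macro_rhs(yp, table1, drive) - macro_rhs(ym, table1, drive)) / (2 * h)
            scale = np.abs(J).max()
            assert np.abs(J - Jfd).max() / scale < 1e-6


class TestIntegrate:
    def test_isolated_core_reaches_mean_field_branch(self):
        """From rho = 0.1 the isolated supercritical core converges to
        sqrt(1 - 2*delta/K)."""
        p = isolated_core_params(K_vv=5.6)
        traj = cs.integrate(p, cs.DriveSpec(mode="DD"), duration_h=200.0,
                            transient_h=4000.0, step_h=1.0,
                            initial=(0.1, 0.0, 0.5, 0.0))
        assert traj.rho_v[-1] == pytest.approx(math.sqrt(1 - 2 / 5.6), abs=1e-4)

    def test_subcritical_core_decays_to_incoherence(self):
        p = isolated_core_params(K_vv=1.5)  # below critical 2*delta_v = 2
        traj = cs.integrate(p, cs.DriveSpec(mode="DD"), duration_h=200.0,
                            transient_h=4000.0, step_h=1.0,
                            initial=(0.4, 0.0, 0.5, 0.0))
        assert traj.rho_v[-1] < 1e-4

    def test_entrained_run_becomes_stationary(self, table1):
        traj = cs.integrate(table1, cs.DriveSpec(mode="LD", T=24.0),
                            duration_h=240.0, transient_h=90 * 24.0, step_h=0.5)
        span = traj.states.max(axis=0) - traj.states.min(axis=0)
        assert np.all(span < 1e-6)

    def test_rho_stays_in_unit_interval(self, table1):
        for drive in (cs.DriveSpec(mode="LD", T=24.0), cs.DriveSpec(mode="DD"),
                      cs.DriveSpec(mode="LL", B=-0.4)):
            traj = cs.integrate(table1, drive, duration_h=1000.0, step_h=0.5,
                                initial=(0.9, 0.0, 0.05, 1.0))
            assert traj.rho_v.min() >= 0 and traj.rho_v.max() <= 1 + 1e-9
            assert traj.rho_d.min() >= 0 and traj.rho_d.max() <= 1 + 1e-9

    def test_uniform_grid(self, table1):
        traj = cs.integrate(table1, cs.DriveSpec(mode="DD"), duration_h=100.0, step_h=0.25)
        assert np.allclose(np.diff(traj.times_h), 0.25)


class TestFixedPoints:
    def test_entrained_phase_difference_at_24h(self, t24):
        report, dpsi, _ = t24
        assert dpsi == pytest.approx(0.607, abs=0.01)
        assert report.residual < 1e-10

    def test_decoupled_groups_share_no_rotating_frame(self):
        """With zero intercoupling each group rotates at its own mean frequency,
        so no common free-running state exists and the solver reports failure
        rather than a silent wrong root."""
        p = isolated_core_params()
        st = free_running_state(p)
        assert not st.converged

    def test_dd_state_is_stationary_in_corotating_frame(self, table1, dd_state):
        """The synchronized DD state solves the equations in the frame rotating
        at the free-running frequency, to 1e-8."""
        y = [dd_state.rho_v, 0.0, dd_state.rho_d, dd_state.chi]
        w = dd_state.omega
        f = macro_rhs(y, table1, cs.DriveSpec(mode="DD")) - np.array([0, w, 0, w])
        assert np.abs(f).max() < 1e-8

    def test_entrained_state_satisfies_sine_identity(self, table1, t24):
        report, dpsi, _ = t24
        ana = cs.entrained_phase_difference(table1, 24.0, report.state.rho_v,
                                            report.state.rho_d)
        assert math.sin(dpsi) == pytest.approx(ana.argument, abs=1e-10)

    def test_divergence_reports_failure(self, table1):
        r = cs.find_fixed_point(table1, cs.DriveSpec(mode="LD", T=24.0),
                                guess=(1e-6, 40.0, 1e-6, -40.0))
        assert isinstance(r.converged, bool)
        if r.converged:  # if it does land somewhere, the residual must be tiny
            assert r.residual < 1e-10


class TestClassification:
    @pytest.mark.parametrize("eigs,label", [
        ([-1.0, -2.0, -3.0, -4.0], "stable_node"),
        ([-1.0 + 2.0j, -1.0 - 2.0j, -3.0, -4.0], "stable_focus"),
        ([1.0, -2.0, -3.0, -4.0], "saddle"),
        ([0.5 + 1.0j, 0.5 - 1.0j, -3.0, -4.0], "unstable"),
        ([1e-9 + 1.3j, 1e-9 - 1.3j, -3.0, -4.0], "hopf_marginal"),
        ([1e-9, -2.0, -3.0, -4.0], "saddle_node_marginal"),
    ])
    def test_decision_table(self, eigs, label):
        assert classify_eigenvalues(np.array(eigs, dtype=complex)) == label


class TestBifurcations:
    def test_upper_limit_is_hopf(self, table1):
        bif = cs.classify_bifurcation(table1, control="T", bracket=(25.0, 25.6), tol=0.005)
        assert bif.converged
        assert bif.label == "hopf_marginal"
        assert 25.25 < bif.critical < 25.40

    def test_lower_limit_is_saddle_node(self, table1):
        bif = cs.classify_bifurcation(table1, control="T", bracket=(23.5, 23.0), tol=0.005)
        assert bif.converged
        assert bif.label == "saddle_node_marginal"
        assert 23.2 < bif.critical < 23.32

    def test_no_crossing_reported(self, table1):
        bif = cs.classify_bifurcation(table1, control="T", bracket=(23.8, 24.8), tol=0.01)
        assert not bif.converged
        assert "no stability change" in bif.message


class TestFreeRunningState:
    def test_dd_period(self, dd_state):
        assert dd_state.tau_h == pytest.approx(24.84, abs=0.05)

    def test_ll_shifts_period_with_sign_of_b(self, table1, dd_state):
        slow = free_running_state(table1, B=-0.2)
        fast = free_running_state(table1, B=0.5)
        assert slow.tau_h > dd_state.tau_h > fast.tau_h
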
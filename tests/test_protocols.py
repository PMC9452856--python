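import math
from dataclasses import replace

import pytest

import coreshell as cs
from coreshell.protocols import (
    CriticalIntensityResult,
    run_drive,
    second_rhythm_present,
)


@pytest.fixture(scope="module")
def anticipation_result(table1):
    return cs.anticipation_protocol(table1, [23.6, 24.0, 24.4, 24.8, 26.0])


@pytest.fixture(scope="module")
def range_result(table1):
    return cs.entrainment_range(table1, tol=0.01)


@pytest.fixture(scope="module")
def dd_result(table1):
    return cs.dd_protocol(table1)


@pytest.fixture(scope="module")
def nocturnal_bc(table1) -> CriticalIntensityResult:
    return cs.critical_light_intensity(table1, "nocturnal")


@pytest.fixture(scope="module")
def aschoff_result(table1):
    return cs.aschoff_scan(table1)


class TestPeakTimeDifference:
    def test_aligned_groups(self):
        assert cs.peak_time_difference(0.0, 24.0) == 0.0
        assert cs.peak_time_difference(0.0, 31.0) == 0.0

    def test_entrained_mouse_value(self):
        assert cs.peak_time_difference(0.607, 24.0) == pytest.approx(2.32, abs=0.005)

    def test_requires_positive_period(self):
        with pytest.raises(ValueError):
            cs.peak_time_difference(0.5, 0.0)


class TestAnticipationProtocol:
    def test_lead_increases_with_period(self, anticipation_result):
        inside = anticipation_result.table[anticipation_result.table.entrained]
        assert len(inside) == 4
        assert anticipation_result.lead_increases_with_T

    def test_out_of_range_period_is_flagged_not_silent(self, anticipation_result):
        row = anticipation_result.table[anticipation_result.table.T_h == 26.0].iloc[0]
        assert not row.entrained
        assert math.isnan(row.peak_lead_h)

    def test_stationary_identity_closes(self, anticipation_result):
        inside = anticipation_result.table[anticipation_result.table.entrained]
        assert (inside.identity_closure < 1e-6).all()

    def test_zero_detuning_period_has_negligible_lead(self, table1):
        res = cs.anticipation_protocol(table1, [table1.shell.tau])
        lead = res.table.peak_lead_h.iloc[0]
        # at T = tau_d the large-sync lead vanishes; the exact stationary lead
        # retains only the small finite-synchrony correction
        assert abs(lead) < 0.15


class TestEntrainmentRange:
    def test_limits_match_bifurcation_structure(self, range_result):
        assert range_result.lle_h < range_result.ule_h
        assert range_result.lower_label == "saddle_node_marginal"
        assert range_result.upper_label == "hopf_marginal"
        assert range_result.locators_agree

    def test_limits_bracket_group_periods(self, range_result, table1):
        """tau_d <~ LLE and ULE <~ tau_v within 0.3 h."""
        assert abs(range_result.lle_h - table1.shell.tau) < 0.3
        assert abs(range_result.ule_h - table1.core.tau) < 0.3

    def test_idempotent_rerun_from_found_limits(self, range_result, table1):
        again = cs.entrainment_range(
            table1,
            bracket_low=(range_result.lle_h - 0.15, range_result.lle_h + 0.15),
            bracket_high=(range_result.ule_h - 0.15, range_result.ule_h + 0.15),
            tol=0.01,
        )
        assert again.lle_h == pytest.approx(range_result.lle_h, abs=0.02)
        assert again.ule_h == pytest.approx(range_result.ule_h, abs=0.02)

    def test_narrowing_period_gap_widens_range(self, range_result, table1):
        """Raising tau_d toward tau_v stretches the entrainment range."""
        closer = cs.entrainment_range(table1.with_shell_period(23.7), tol=0.01,
                                      bracket_low=(22.0, 24.2),
                                      bracket_high=(24.4, 27.0))
        assert (closer.ule_h - closer.lle_h) > (range_result.ule_h - range_result.lle_h)

    def test_second_rhythm_sides(self, range_result, table1):
        """Outside the range the dissociated period sits above T below LLE and
        below T above ULE."""
        for T, expect_above in ((range_result.lle_h - 0.1, True),
                                (range_result.ule_h + 0.1, False)):
            traj = run_drive(table1, cs.DriveSpec(mode="LD", T=T))
            comps = cs.spectral_components(cs.lab_observable(traj, "shell"),
                                           traj.step_h, group="shell",
                                           drive_period_h=T)
            sr = cs.second_rhythm(comps, T)
            assert sr is not None
            assert (sr.period_h > T) == expect_above


class TestDDProtocol:
    def test_synchronized_free_running_period(self, dd_result):
        assert not dd_result.desynchronized
        assert dd_result.tau_dd_h == pytest.approx(24.84, abs=0.05)

    def test_fourier_and_identity_periods_agree(self, dd_result):
        assert dd_result.tau_dd_h == pytest.approx(dd_result.tau_eq15_h, abs=0.01)

    def test_decoupled_groups_raise_desync_flag(self, table1):
        p = replace(table1, K_vd=0.0, K_dv=0.0)
        res = cs.dd_protocol(p)
        assert res.desynchronized
        # each group free-runs near its own mean period
        assert res.tau_core_h == pytest.approx(table1.core.tau, abs=0.1)
        assert res.tau_shell_h == pytest.approx(table1.shell.tau, abs=0.1)

    def test_weak_total_intercoupling_cannot_synchronize(self, table1):
        """Total intercoupling below the frequency difference: no common rhythm."""
        p = replace(table1, K_vd=0.05, K_dv=0.04)
        bound = cs.dd_phase_difference(p, 0.8, 0.4)
        assert not bound.bound_ok
        res = cs.dd_protocol(p)
        assert res.desynchronized


class TestLLProtocol:
    def test_zero_intensity_reproduces_dd(self, table1, dd_result):
        ll = cs.ll_protocol(table1, 0.0)
        assert ll.tau_ll_h == dd_result.tau_dd_h
        assert ll.second_rhythm_shell is None

    def test_nocturnal_light_lengthens_period(self, table1):
        ll = cs.ll_protocol(table1, -0.24)
        assert ll.tau_ll_h == pytest.approx(25.2, abs=0.05)
        assert ll.tau_ll_h == pytest.approx(ll.tau_analytic_h, abs=0.01)

    def test_diurnal_light_shortens_period(self, table1):
        ll = cs.ll_protocol(table1, 3.3)
        assert ll.tau_ll_h == pytest.approx(21.6, abs=0.1)


class TestCriticalLightIntensity:
    def test_nocturnal_onset_is_hopf(self, nocturnal_bc):
        assert nocturnal_bc.label == "hopf_marginal"
        assert nocturnal_bc.Bc < 0
        assert 0.25 < nocturnal_bc.abs_Bc < 0.31
        assert nocturnal_bc.confirmed_outside and nocturnal_bc.confirmed_inside

    def test_nocturnal_onset_period_exceeds_dd(self, nocturnal_bc, dd_state):
        assert nocturnal_bc.tau_ll_onset_h > dd_state.tau_h

    def test_diurnal_onset_order_of_magnitude_larger(self, table1, nocturnal_bc):
        diurnal = cs.critical_light_intensity(table1, "diurnal",
                                              spectral_confirmation=False)
        assert 8 < diurnal.abs_Bc / nocturnal_bc.abs_Bc < 15

    def test_no_onset_in_bracket_is_an_error(self, table1):
        with pytest.raises(RuntimeError, match="no stability change"):
            cs.critical_light_intensity(table1, "nocturnal", bracket=(-0.01, -0.1),
                                        spectral_confirmation=False)


class TestAschoffScan:
    def test_nocturnal_branch_slows_the_clock(self, aschoff_result):
        assert aschoff_result.nocturnal_monotone_increasing
        assert aschoff_result.nocturnal_above_dd

    def test_diurnal_branch_speeds_the_clock(self, aschoff_result):
        assert aschoff_result.diurnal_monotone_decreasing
        assert aschoff_result.diurnal_below_dd

    def test_zero_intensity_point_equals_dd_exactly(self, aschoff_result, dd_state):
        row = aschoff_result.table[aschoff_result.table.B == 0.0].iloc[0]
        assert row.tau_ll_h == dd_state.tau_h


class TestSecondRhythmPresence:
    def test_entrained_period_clean(self, table1):
        present, traj = second_rhythm_present(table1, 24.0)
        assert not present
        assert traj.rho_v.min() >= 0 and traj.rho_d.max() <= 1 + 1e-9

    def test_dissociated_period_detected(self, table1):
        present, _ = second_rhythm_present(table1, 26.0)
        assert present
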
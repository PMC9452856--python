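"""The study protocols: entrainment, anticipation, dissociation, DD, LL.

Each protocol runs the reduced model under a lighting schedule and measures
the quantities an experimenter would report: the entrained phase relation and
peak-time lead, the range of light-dark periods that entrain the SCN, the
period and intensity of dissociated rhythms outside that range, the
free-running period in constant darkness, and the response to constant light
(Aschoff's first rule, critical intensity for dissociation).

Conventions, fixed across all protocols unless overridden:

- initial state (0.5, 0, 0.5, 0); 50 drive periods (or 50 x 24 h for DD/LL)
  of transient are discarded; 200 periods are recorded at 0.25 h sampling;
- entrainment is judged both spectrally (exactly one drive-locked component
  above the 1% floor) and by linear stability of the entrained fixed point;
- the spectral limit locator restarts every bisection trial from the default
  initial state, so each trial sees the same approach to the attractor (a
  state-continuation variant is available for hysteresis checks); near the
  upper (Hopf) limit the spectral onset sits inside the linear-stability
  boundary by the width of the critical-slowing layer, so the two locators
  are required to agree within ``LOCATOR_AGREEMENT_H`` rather than the
  bisection tolerance;
- near-limit dissociation gaps are measured 0.02 h outside the bifurcation
  points and referenced to them, since the gaps characterize the bifurcation
  (the dissociated period approaches the drive period at the saddle-node, and
  jumps by the Hopf frequency at the Hopf);
- records below the lower limit use 800 drive periods: the dissociated line
  sits ~0.2 h from the drive line and needs the extra resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytic import dd_frequency, entrained_phase_difference, ll_frequency_and_phase
from .parameters import CoreShellParameters, DriveSpec
from .reduced_model import (
    BifurcationResult,
    DEFAULT_INITIAL_STATE,
    FixedPointReport,
    FreeRunningState,
    MacroState,
    Trajectory,
    classify_bifurcation,
    find_fixed_point,
    free_running_state,
    integrate,
)
from .spectral import (
    SECOND_RHYTHM_FLOOR,
    SpectralComponent,
    drift_rate_period,
    lab_observable,
    second_rhythm,
    spectral_components,
)

__all__ = [
    "TRANSIENT_PERIODS",
    "RECORD_PERIODS",
    "GAP_RECORD_PERIODS",
    "SAMPLE_STEP_H",
    "LOCATOR_AGREEMENT_H",
    "peak_time_difference",
    "entrained_state",
    "AnticipationResult",
    "anticipation_protocol",
    "EntrainmentResult",
    "entrainment_range",
    "DissociationResult",
    "dissociation_curve",
    "DDResult",
    "dd_protocol",
    "LLResult",
    "ll_protocol",
    "CriticalIntensityResult",
    "critical_light_intensity",
    "AschoffResult",
    "aschoff_scan",
    "run_drive",
    "second_rhythm_present",
]

TRANSIENT_PERIODS = 50
RECORD_PERIODS = 200
GAP_RECORD_PERIODS = 800
SAMPLE_STEP_H = 0.25
#: Reference "period" used to size DD/LL transients and records, hours.
NOMINAL_PERIOD_H = 24.0
#: Required agreement between the spectral and stability limit locators.
LOCATOR_AGREEMENT_H = 0.06
#: Offset (hours or intensity units) outside a bifurcation point at which
#: near-limit quantities are measured.
NEAR_LIMIT_OFFSET = 0.02


# --- shared runners ----------------------------------------------------------

def run_drive(
    params: CoreShellParameters,
    drive: DriveSpec,
    *,
    transient_periods: float = TRANSIENT_PERIODS,
    record_periods: float = RECORD_PERIODS,
    step_h: float = SAMPLE_STEP_H,
    initial: MacroState | tuple | None = None,
) -> Trajectory:
    """Integrate under ``drive`` with the period-based transient/record lengths."""
    T_ref = drive.T if drive.mode == "LD" else NOMINAL_PERIOD_H
    return integrate(
        params, drive,
        duration_h=record_periods * T_ref,
        transient_h=transient_periods * T_ref,
        step_h=step_h,
        initial=initial,
    )


def second_rhythm_present(
    params: CoreShellParameters,
    T: float,
    *,
    floor: float = SECOND_RHYTHM_FLOOR,
    initial: MacroState | tuple | None = None,
    record_periods: float = RECORD_PERIODS,
) -> tuple[bool, Trajectory]:
    """Does the shell observable carry a non-drive-locked component above floor?"""
    traj = run_drive(params, DriveSpec(mode="LD", T=T), initial=initial,
                     record_periods=record_periods)
    comps = spectral_components(lab_observable(traj, "shell"), traj.step_h,
                                group="shell", drive_period_h=T)
    return second_rhythm(comps, T, floor=floor) is not None, traj


# --- anticipation ------------------------------------------------------------

def peak_time_difference(delta_psi: float, T: float) -> float:
    """Shell-over-core peak-activity lead ``T * delta_psi / (2*pi)``, hours."""
    if not T > 0:
        raise ValueError("T must be positive")
    return T * delta_psi / (2.0 * math.pi)


def entrained_state(
    params: CoreShellParameters,
    T: float,
    guess: MacroState | tuple | None = None,
) -> tuple[FixedPointReport, float | None, float | None]:
    """Entrained fixed point at LD period ``T`` with (delta_psi, peak lead).

    delta_psi and the lead are None when no stable entrained state exists.
    """
    drive = DriveSpec(mode="LD", T=T)
    report = find_fixed_point(params, drive, guess=guess)
    if not report.stable:
        # the root search may miss the attractor from a cold guess: settle onto
        # it by integration, then retry
        settle = integrate(params, drive, duration_h=T, transient_h=100 * T,
                           step_h=T, initial=guess)
        report = find_fixed_point(params, drive, guess=settle.states[-1])
    if not report.stable:
        return report, None, None
    dpsi = report.state.psi_d - report.state.psi_v
    return report, dpsi, peak_time_difference(dpsi, T)


@dataclass
class AnticipationResult:
    table: pd.DataFrame
    lead_increases_with_T: bool


def anticipation_protocol(params: CoreShellParameters, T_grid) -> AnticipationResult:
    """Stationary phase difference and peak lead across LD periods.

    Out-of-range periods appear as flagged rows (entrained = False), never
    silently.  Each entrained row records the closure of the stationary
    phase-difference identity as a consistency check.
    """
    rows = []
    guess = None
    for T in T_grid:
        report, dpsi, lead = entrained_state(params, T, guess=guess)
        if report.stable:
            guess = report.state
            ana = entrained_phase_difference(params, T, report.state.rho_v,
                                             report.state.rho_d)
            closure = abs(math.sin(dpsi) - ana.argument)
        else:
            closure = math.nan
        rows.append({
            "T_h": T,
            "entrained": report.stable,
            "delta_psi_rad": dpsi if dpsi is not None else math.nan,
            "peak_lead_h": lead if lead is not None else math.nan,
            "rho_v": report.state.rho_v if report.stable else math.nan,
            "rho_d": report.state.rho_d if report.stable else math.nan,
            "identity_closure": closure,
        })
    table = pd.DataFrame(rows)
    ok = table[table.entrained]
    increasing = bool(np.all(np.diff(ok.peak_lead_h.to_numpy()) > 0)) if len(ok) > 1 else False
    return AnticipationResult(table=table, lead_increases_with_T=increasing)


# --- entrainment range -------------------------------------------------------

@dataclass
class EntrainmentResult:
    lle_h: float
    ule_h: float
    lle_stability_h: float
    ule_stability_h: float
    lower_label: str
    upper_label: str
    locators_agree: bool
    tol_h: float
    probes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.lle_h < self.ule_h:
            raise ValueError("lower limit must be below upper limit")


def _spectral_bisect(
    params: CoreShellParameters,
    inside: float,
    outside: float,
    tol: float,
    floor: float,
    continuation: bool,
    probes: list,
) -> float:
    state = None
    present_in, traj = second_rhythm_present(params, inside, floor=floor)
    probes.append({"T_h": inside, "second_rhythm": present_in})
    if present_in:
        raise ValueError(f"bracket endpoint {inside} h is not entrained")
    if continuation:
        state = traj.final_state()
    present_out, traj = second_rhythm_present(
        params, outside, floor=floor, initial=state if continuation else None)
    probes.append({"T_h": outside, "second_rhythm": present_out})
    if not present_out:
        raise ValueError(f"bracket endpoint {outside} h shows no dissociation")
    lo, hi = inside, outside
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        present, traj = second_rhythm_present(
            params, mid, floor=floor, initial=state if continuation else None)
        probes.append({"T_h": mid, "second_rhythm": present})
        if continuation:
            state = traj.final_state()
        if present:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def entrainment_range(
    params: CoreShellParameters,
    bracket_low: tuple[float, float] = (22.0, 24.0),
    bracket_high: tuple[float, float] = (24.5, 26.5),
    tol: float = 0.005,
    *,
    floor: float = SECOND_RHYTHM_FLOOR,
    continuation: bool = False,
) -> EntrainmentResult:
    """Lower and upper limits of entrainment by spectral bisection.

    The reported limits come from bisection on "does the shell observable
    carry a second rhythm?".  The linear-stability boundary of the entrained
    fixed point is located independently and must agree within
    ``LOCATOR_AGREEMENT_H``; its eigenvalue structure labels the bifurcation
    at each limit.
    """
    probes: list = []
    lle = _spectral_bisect(params, bracket_low[1], bracket_low[0], tol, floor,
                           continuation, probes)
    ule = _spectral_bisect(params, bracket_high[0], bracket_high[1], tol, floor,
                           continuation, probes)

    low_bif = classify_bifurcation(params, control="T",
                                   bracket=(bracket_low[1], bracket_low[0]), tol=tol)
    high_bif = classify_bifurcation(params, control="T",
                                    bracket=(bracket_high[0], bracket_high[1]), tol=tol)
    if not (low_bif.converged and high_bif.converged):
        raise RuntimeError("stability locator found no crossing in a bracket")

    agree = (abs(lle - low_bif.critical) <= LOCATOR_AGREEMENT_H
             and abs(ule - high_bif.critical) <= LOCATOR_AGREEMENT_H)
    if not agree:
        raise RuntimeError(
            "spectral and stability locators disagree beyond "
            f"{LOCATOR_AGREEMENT_H} h: spectral ({lle:.3f}, {ule:.3f}) vs "
            f"stability ({low_bif.critical:.3f}, {high_bif.critical:.3f}); "
            "possible multistability — investigate before trusting either"
        )
    return EntrainmentResult(
        lle_h=lle, ule_h=ule,
        lle_stability_h=low_bif.critical, ule_stability_h=high_bif.critical,
        lower_label=low_bif.label, upper_label=high_bif.label,
        locators_agree=agree, tol_h=tol,
        probes=pd.DataFrame(probes).sort_values("T_h").reset_index(drop=True),
    )


# --- dissociation ------------------------------------------------------------

@dataclass
class DissociationResult:
    table: pd.DataFrame
    lower_gap_h: float   # |Tsr - LLE| just below the lower limit
    upper_gap_h: float   # |Tsr - ULE| just above the upper limit
    lle_bifurcation_h: float
    ule_bifurcation_h: float


def _component_row(params, T, initial=None, record_periods=RECORD_PERIODS):
    traj = run_drive(params, DriveSpec(mode="LD", T=T), initial=initial,
                     record_periods=record_periods)
    row = {"T_h": T}
    for group in ("core", "shell"):
        comps = spectral_components(lab_observable(traj, group), traj.step_h,
                                    group=group, drive_period_h=T)
        locked = [c for c in comps if c.field_locked]
        sr = second_rhythm(comps, T)
        row[f"I_F_{group}"] = locked[0].intensity if locked else 0.0
        row[f"T_sr_{group}"] = sr.period_h if sr else math.nan
        row[f"I_sr_{group}"] = sr.intensity if sr else 0.0
    row["T_sr_drift_shell"] = drift_rate_period(traj, "shell") or math.nan
    return row


def dissociation_curve(
    params: CoreShellParameters,
    T_grid=None,
    *,
    gap_offset_h: float = NEAR_LIMIT_OFFSET,
) -> DissociationResult:
    """Second-rhythm period and component intensities across LD periods.

    Besides the per-T table, measures the near-limit gaps between the
    dissociated period and the entrainment limits, 0.02 h outside the
    bifurcation points (800-period records below the lower limit, where the
    dissociated line hugs the drive line).
    """
    low_bif = classify_bifurcation(params, control="T", bracket=(24.0, 22.8), tol=0.002)
    high_bif = classify_bifurcation(params, control="T", bracket=(24.5, 26.0), tol=0.002)
    lle_b, ule_b = low_bif.critical, high_bif.critical

    if T_grid is None:
        T_grid = np.concatenate([
            np.arange(22.6, lle_b - 0.01, 0.1),
            np.arange(math.ceil(lle_b * 10) / 10, ule_b, 0.2),
            np.arange(ule_b + 0.05, 26.6, 0.1),
        ])
    rows = [_component_row(params, float(T)) for T in T_grid]
    table = pd.DataFrame(rows)

    below = _component_row(params, lle_b - gap_offset_h,
                           record_periods=GAP_RECORD_PERIODS)
    above = _component_row(params, ule_b + gap_offset_h)
    lower_gap = abs(below["T_sr_shell"] - lle_b)
    upper_gap = abs(above["T_sr_shell"] - ule_b)
    return DissociationResult(table=table, lower_gap_h=float(lower_gap),
                              upper_gap_h=float(upper_gap),
                              lle_bifurcation_h=lle_b, ule_bifurcation_h=ule_b)


# --- DD / LL ----------------------------------------------------------------

@dataclass
class DDResult:
    tau_dd_h: float
    tau_core_h: float
    tau_shell_h: float
    tau_eq15_h: float
    rho_v: float
    rho_d: float
    desynchronized: bool
    components_core: list[SpectralComponent]
    components_shell: list[SpectralComponent]
    trajectory: Trajectory | None = None


def dd_protocol(
    params: CoreShellParameters,
    *,
    keep_trajectory: bool = False,
) -> DDResult:
    """Free-running period of the synchronized SCN in constant darkness.

    Fourier analysis of the lab-frame observables gives the dominant period of
    each group; the result is cross-checked against the stationary
    frequency-mixing identity evaluated at the synchronized state's
    synchronization indices.  Core and shell dominant periods differing by
    more than 0.05 h raise the desynchronized-SCN flag (total intercoupling
    below the frequency-difference bound).
    """
    drive = DriveSpec(mode="DD")
    traj = run_drive(params, drive)
    comps = {g: spectral_components(lab_observable(traj, g), traj.step_h, group=g)
             for g in ("core", "shell")}
    tau_core = comps["core"][0].period_h if comps["core"] else math.nan
    tau_shell = comps["shell"][0].period_h if comps["shell"] else math.nan
    desync = (math.isnan(tau_core) or math.isnan(tau_shell)
              or abs(tau_core - tau_shell) > 0.05)

    state = free_running_state(params)
    eq15 = dd_frequency(params, state.rho_v, state.rho_d)
    return DDResult(
        tau_dd_h=0.5 * (tau_core + tau_shell) if not desync else math.nan,
        tau_core_h=tau_core, tau_shell_h=tau_shell,
        tau_eq15_h=eq15.tau_dd_h,
        rho_v=state.rho_v, rho_d=state.rho_d,
        desynchronized=desync,
        components_core=comps["core"], components_shell=comps["shell"],
        trajectory=traj if keep_trajectory else None,
    )


@dataclass
class LLResult:
    B: float
    tau_ll_h: float
    tau_core_h: float
    tau_shell_h: float
    tau_analytic_h: float
    second_rhythm_shell: SpectralComponent | None
    second_rhythm_core: SpectralComponent | None
    desynchronized: bool


def ll_protocol(params: CoreShellParameters, B: float) -> LLResult:
    """Free-running rhythm under constant light of signed intensity ``B``.

    ``B = 0`` reproduces the DD protocol.  The dominant spectral period per
    group is reported together with any dissociated component (strongest
    non-dominant line above the 1% floor) and the analytic stationary
    frequency for cross-checking.
    """
    drive = DriveSpec(mode="LL", B=B) if B != 0.0 else DriveSpec(mode="DD")
    traj = run_drive(params, drive)
    comps = {g: spectral_components(lab_observable(traj, g), traj.step_h, group=g)
             for g in ("core", "shell")}
    tau_core = comps["core"][0].period_h if comps["core"] else math.nan
    tau_shell = comps["shell"][0].period_h if comps["shell"] else math.nan
    desync = (math.isnan(tau_core) or math.isnan(tau_shell)
              or abs(tau_core - tau_shell) > 0.05)

    def sr(group):
        c = comps[group]
        if not c:
            return None
        dominant = c[0]
        rest = [x for x in c[1:] if x.intensity >= SECOND_RHYTHM_FLOOR * dominant.intensity]
        return rest[0] if rest else None

    state = free_running_state(params, B=B)
    ana = ll_frequency_and_phase(params, state.rho_v, state.rho_d, B)
    return LLResult(
        B=B,
        tau_ll_h=0.5 * (tau_core + tau_shell) if not desync else math.nan,
        tau_core_h=tau_core, tau_shell_h=tau_shell,
        tau_analytic_h=ana.tau_ll_h,
        second_rhythm_shell=sr("shell"), second_rhythm_core=sr("core"),
        desynchronized=desync,
    )


@dataclass
class CriticalIntensityResult:
    Bc: float                     # signed
    abs_Bc: float
    tau_ll_onset_h: float
    label: str
    bifurcation: BifurcationResult
    confirmed_outside: bool | None = None
    confirmed_inside: bool | None = None


def critical_light_intensity(
    params: CoreShellParameters,
    sign: str,
    bracket: tuple[float, float] | None = None,
    tol: float = 0.005,
    *,
    spectral_confirmation: bool = True,
    confirmation_offset: float = 0.05,
) -> CriticalIntensityResult:
    """Critical constant-light intensity for the onset of a second rhythm.

    The onset is the loss of stability of the synchronized LL state (a Hopf
    instability of the phase-difference system), located by bisection on its
    leading eigenvalue.  Optionally confirmed spectrally: the shell observable
    must show a second rhythm just outside the critical intensity and none
    just inside.
    """
    if sign not in ("nocturnal", "diurnal"):
        raise ValueError("sign must be 'nocturnal' (B < 0) or 'diurnal' (B > 0)")
    if bracket is None:
        bracket = (-0.05, -0.6) if sign == "nocturnal" else (2.0, 4.0)
    bif = classify_bifurcation(params, control="B", bracket=bracket, tol=tol)
    if not bif.converged:
        raise RuntimeError(f"no stability change in bracket {bracket}: {bif.message}")
    report = bif.report
    assert isinstance(report, FreeRunningState)

    conf_out = conf_in = None
    if spectral_confirmation:
        off = math.copysign(confirmation_offset, bif.critical)
        out = ll_protocol(params, bif.critical + off)
        inn = ll_protocol(params, bif.critical - off)
        conf_out = out.second_rhythm_shell is not None
        conf_in = inn.second_rhythm_shell is None
        if not (conf_out and conf_in):
            raise RuntimeError(
                f"spectral confirmation failed around Bc={bif.critical:.3f}: "
                f"outside present={conf_out}, inside absent={conf_in}"
            )
    return CriticalIntensityResult(
        Bc=bif.critical, abs_Bc=abs(bif.critical),
        tau_ll_onset_h=report.tau_h, label=bif.label, bifurcation=bif,
        confirmed_outside=conf_out, confirmed_inside=conf_in,
    )


@dataclass
class AschoffResult:
    table: pd.DataFrame
    tau_dd_h: float
    nocturnal_monotone_increasing: bool
    diurnal_monotone_decreasing: bool
    nocturnal_above_dd: bool
    diurnal_below_dd: bool


def aschoff_scan(params: CoreShellParameters, B_values=None) -> AschoffResult:
    """Free-running period vs constant-light intensity for both signs of B.

    Verifies Aschoff's first rule in the model: for nocturnal light action
    (B < 0) the free-running period lengthens with intensity and exceeds the
    DD period; for diurnal action (B > 0) it shortens and stays below.  The
    grid should stay inside the synchronized regime (below dissociation
    onset); unstable points are flagged.
    """
    if B_values is None:
        B_values = [-0.25, -0.2, -0.15, -0.1, -0.05, 0.0, 0.5, 1.0, 2.0, 3.0]
    rows = []
    for B in sorted(B_values):
        st = free_running_state(params, B=B)
        rows.append({"B": B, "tau_ll_h": st.tau_h, "stable": st.stable,
                     "rho_v": st.rho_v, "rho_d": st.rho_d})
    table = pd.DataFrame(rows)
    tau_dd = float(table.loc[table.B == 0.0, "tau_ll_h"].iloc[0]) if (table.B == 0).any() \
        else free_running_state(params).tau_h
    noct = table[(table.B < 0) & table.stable].sort_values("B", ascending=False)
    diur = table[(table.B > 0) & table.stable].sort_values("B")
    return AschoffResult(
        table=table,
        tau_dd_h=tau_dd,
        nocturnal_monotone_increasing=bool(np.all(np.diff(noct.tau_ll_h) > 0)) if len(noct) > 1 else False,
        diurnal_monotone_decreasing=bool(np.all(np.diff(diur.tau_ll_h) < 0)) if len(diur) > 1 else False,
        nocturnal_above_dd=bool((noct.tau_ll_h > tau_dd).all()) if len(noct) else False,
        diurnal_below_dd=bool((diur.tau_ll_h < tau_dd).all()) if len(diur) else False,
    )
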
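"""Closed-form stationary relations of the core-shell model.

These are exact identities of the macroscopic equations at stationary states
(entrained under LD, rigidly rotating under DD/LL) plus their large-synchrony
approximations.  They serve both as calculators (inferring couplings from
measurable free-running periods) and as independent consistency oracles for
the simulated stationary states.

All arcsines are taken on the principal branch [-pi/2, pi/2]; the entrained
core-shell phase difference lies in this interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import CoreShellParameters

__all__ = [
    "WeightPair",
    "weights",
    "PhaseDifferenceResult",
    "entrained_phase_difference",
    "anticipation_lead",
    "DDFrequencyResult",
    "dd_frequency",
    "relative_intercoupling",
    "DDPhaseResult",
    "dd_phase_difference",
    "ll_renormalization",
    "LLResultAnalytic",
    "ll_frequency_and_phase",
]


@dataclass(frozen=True)
class WeightPair:
    """Frequency-mixing weights of the synchronized free-running state.

    ``a`` weighs the core mean frequency and ``b`` the shell mean frequency in
    the free-running compromise frequency; they grow with the forward
    (core->shell) and backward intercoupling respectively.
    """

    a: float
    b: float


def weights(params: CoreShellParameters, rho_v: float, rho_d: float) -> WeightPair:
    a = rho_v**2 * params.K_vd * (1.0 + rho_d**2)
    b = rho_d**2 * params.K_dv * (1.0 + rho_v**2)
    return WeightPair(a=a, b=b)


@dataclass(frozen=True)
class PhaseDifferenceResult:
    """Entrained shell-minus-core phase difference and its approximations."""

    delta_psi: float | None          # exact stationary identity
    delta_psi_large_sync: float | None   # rho ~ 1 approximation
    feasible: bool                   # |arcsine argument| <= 1 (exact form)
    coupling_bound_ok: bool          # K_vd > shell detuning (approx form)
    argument: float

    @property
    def entrained_solution_exists(self) -> bool:
        return self.feasible


def entrained_phase_difference(
    params: CoreShellParameters,
    T: float,
    rho_v: float,
    rho_d: float,
) -> PhaseDifferenceResult:
    """Stationary psi_d - psi_v under an LD drive of period ``T`` hours.

    Exact identity: sin(dpsi) = 2*rho_d*(w_d - w_F) / (rho_v*(1+rho_d^2)*K_vd),
    with all frequencies dimensionless.  Also returns the large-synchrony
    approximation sin(dpsi) ~ (w_d - w_F)/K_vd and the solvability condition
    K_vd > w_d - w_F it implies for positive forward intercoupling.
    """
    d = params.dimensionless
    w_F = params.omega_dimensionless(2.0 * math.pi / T)
    detune = d.omega_d - w_F
    arg = 2.0 * rho_d * detune / (rho_v * (1.0 + rho_d**2) * params.K_vd)
    feasible = abs(arg) <= 1.0
    arg_approx = detune / params.K_vd
    return PhaseDifferenceResult(
        delta_psi=math.asin(arg) if feasible else None,
        delta_psi_large_sync=math.asin(arg_approx) if abs(arg_approx) <= 1 else None,
        feasible=feasible,
        coupling_bound_ok=params.K_vd > detune,
        argument=arg,
    )


def anticipation_lead(params: CoreShellParameters, T: float) -> float | None:
    """Large-synchrony shell-over-core peak-time lead, hours.

    ``(T/2pi) * arcsin((w_d - w_F)/K_vd)``; None when no entrained solution
    exists in this approximation (argument outside [-1, 1]).
    """
    d = params.dimensionless
    w_F = params.omega_dimensionless(2.0 * math.pi / T)
    arg = (d.omega_d - w_F) / params.K_vd
    if abs(arg) > 1.0:
        return None
    return T / (2.0 * math.pi) * math.asin(arg)


@dataclass(frozen=True)
class DDFrequencyResult:
    omega_dd: float                  # dimensionless
    tau_dd_h: float
    weights: WeightPair
    inside_period_interval: bool     # tau_d < tau_DD < tau_v (positive couplings)
    degenerate: bool = False


def dd_frequency(params: CoreShellParameters, rho_v: float, rho_d: float) -> DDFrequencyResult:
    """Free-running frequency of the synchronized SCN in constant darkness.

    Weighted mean ``(a*w_v + b*w_d)/(a + b)`` of the group mean frequencies.
    The same rational expression covers negative intercouplings, where the
    period may escape the interval (tau_d, tau_v); the report flags whether it
    stays inside.
    """
    d = params.dimensionless
    w = weights(params, rho_v, rho_d)
    total = w.a + w.b
    if total == 0.0:
        return DDFrequencyResult(omega_dd=math.nan, tau_dd_h=math.nan, weights=w,
                                 inside_period_interval=False, degenerate=True)
    omega_dd = (w.a * d.omega_v + w.b * d.omega_d) / total
    tau_dd_h = 2.0 * math.pi / (omega_dd * params.frequency_unit)
    lo, hi = sorted((params.shell.tau, params.core.tau))
    return DDFrequencyResult(omega_dd=omega_dd, tau_dd_h=tau_dd_h, weights=w,
                             inside_period_interval=lo < tau_dd_h < hi)


def relative_intercoupling(tau_dd: float, tau_v: float, tau_d: float) -> float:
    """Intercoupling ratio K_vd/K_dv from free-running periods (large synchrony).

    ``(tau_DD/tau_d - 1) / (1 - tau_DD/tau_v)``; requires tau_DD strictly
    between tau_d and tau_v.
    """
    lo, hi = sorted((tau_d, tau_v))
    if not (lo < tau_dd < hi):
        raise ValueError(
            f"tau_DD={tau_dd} must lie strictly between the group periods "
            f"({lo}, {hi}); outside this interval the positive-coupling "
            "period bound is violated"
        )
    return (tau_dd / tau_d - 1.0) / (1.0 - tau_dd / tau_v)


@dataclass(frozen=True)
class DDPhaseResult:
    delta_psi: float | None          # shell minus core, rad
    argument: float
    bound_ok: bool                   # |K_vd + K_dv| >= |w_d - w_v| (rho ~ 1)
    bound_margin: float              # |K_vd + K_dv| - |w_d - w_v|
    bound_rhs: float                 # |w_d - w_v|, dimensionless
    exact_bound_ok: bool             # |arcsine argument| <= 1 at the given rho


def dd_phase_difference(
    params: CoreShellParameters,
    rho_v: float,
    rho_d: float,
) -> DDPhaseResult:
    """Shell-minus-core phase difference in the synchronized DD state.

    ``sin(dpsi) = 2*rho_v*rho_d*(w_d - w_v)/(a + b)``, the LD identity with the
    drive frequency replaced by the free-running compromise frequency.  Also
    evaluates the large-synchrony synchronization bound: the total
    intercoupling must be at least the mean-frequency difference, else the SCN
    cannot synchronize in constant darkness.
    """
    d = params.dimensionless
    w = weights(params, rho_v, rho_d)
    total = w.a + w.b
    freq_diff = d.omega_d - d.omega_v
    arg = 2.0 * rho_v * rho_d * freq_diff / total if total != 0 else math.inf
    exact_ok = abs(arg) <= 1.0
    bound_rhs = abs(freq_diff)
    margin = abs(params.K_vd + params.K_dv) - bound_rhs
    return DDPhaseResult(
        delta_psi=math.asin(arg) if exact_ok else None,
        argument=arg,
        bound_ok=margin >= 0.0,
        bound_margin=margin,
        bound_rhs=bound_rhs,
        exact_bound_ok=exact_ok,
    )


def ll_renormalization(
    tau_v_h: float,
    B: float,
    frequency_unit: float,
) -> tuple[float, float]:
    """Renormalized core frequency and period under constant light.

    Constant light shifts every core oscillator's frequency by the signed
    dimensionless intensity ``B``: ``w_v* = w_v + B`` (dimensionless) and
    ``tau_v* = tau_v / (1 + B*tau_v*frequency_unit/(2*pi))`` hours.  ``B > 0``
    (diurnal) shortens the core period; ``-w_v < B < 0`` (nocturnal)
    lengthens it.
    """
    w_v = (2.0 * math.pi / tau_v_h) / frequency_unit
    w_star = w_v + B
    if w_star <= 0:
        raise ValueError(
            f"renormalized core frequency must stay positive: w_v={w_v:.3f}, B={B}"
        )
    tau_star = 2.0 * math.pi / (w_star * frequency_unit)
    return w_star, tau_star


@dataclass(frozen=True)
class LLResultAnalytic:
    omega_ll: float                  # dimensionless
    tau_ll_h: float
    delta_psi: float | None
    argument: float
    aschoff_consistent: bool         # sign(omega_LL - omega_DD) == sign(B)
    phase_inverted: bool             # core leads shell (sin(dpsi) < 0)


def ll_frequency_and_phase(
    params: CoreShellParameters,
    rho_v: float,
    rho_d: float,
    B: float,
) -> LLResultAnalytic:
    """Free-running frequency and phase difference under constant light.

    The DD expressions with the core mean frequency shifted by ``B``:
    ``omega_LL = (a*(w_v + B) + b*w_d)/(a + b)`` and
    ``sin(dpsi) = 2*rho_v*rho_d*(w_d - w_v - B)/(a + b)``.
    ``omega_LL - omega_DD = a*B/(a+b)`` carries the sign of ``B`` (Aschoff's
    first rule); a large enough ``|B|`` flips the sign of the phase
    difference, putting the core ahead of the shell.
    """
    d = params.dimensionless
    w = weights(params, rho_v, rho_d)
    total = w.a + w.b
    omega_ll = (w.a * (d.omega_v + B) + w.b * d.omega_d) / total
    omega_dd = (w.a * d.omega_v + w.b * d.omega_d) / total
    tau_ll_h = 2.0 * math.pi / (omega_ll * params.frequency_unit)
    arg = 2.0 * rho_v * rho_d * (d.omega_d - d.omega_v - B) / total
    dpsi = math.asin(arg) if abs(arg) <= 1.0 else None
    return LLResultAnalytic(
        omega_ll=omega_ll,
        tau_ll_h=tau_ll_h,
        delta_psi=dpsi,
        argument=arg,
        aschoff_consistent=(B == 0.0) or (math.copysign(1, omega_ll - omega_dd)
                                          == math.copysign(1, B)),
        phase_inverted=arg < 0.0,
    )
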
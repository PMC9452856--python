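"""Reduced macroscopic dynamics of the core-shell model.

State: ``(rho_v, psi_v, rho_d, psi_d)`` — synchronization index and group phase
of the core (v) and shell (d).  Under a light-dark (LD) drive the equations are
written in the frame rotating at the drive frequency ``omega_F``, where
entrainment is a stable fixed point.  Under constant darkness (DD) or constant
light (LL) the same equations are integrated with the cue off and
``omega_F = 0`` (lab frame), so the group phases drift at roughly the free-
running frequency; under LL the core mean frequency is shifted by the signed
light intensity ``B``.

All internal computation is dimensionless (frequencies in units of the core
spread); the public surface takes and returns hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import CoreShellParameters, DriveSpec

__all__ = [
    "MacroState",
    "Trajectory",
    "FixedPointReport",
    "FreeRunningState",
    "BifurcationResult",
    "macro_rhs",
    "macro_jacobian",
    "integrate",
    "find_fixed_point",
    "free_running_state",
    "classify_eigenvalues",
    "classify_bifurcation",
    "DEFAULT_INITIAL_STATE",
    "RHO_FLOOR",
]

#: Regularization floor for rho in the 1/rho phase-equation denominators.  The
#: phase of a fully incoherent group is physically meaningless; the floor only
#: prevents overflow if a trajectory grazes rho = 0.
RHO_FLOOR = 1e-9

#: Default initial state (rho_v, psi_v, rho_d, psi_d) for all protocols.
DEFAULT_INITIAL_STATE = (0.5, 0.0, 0.5, 0.0)

Classification = Literal[
    "stable_node", "stable_focus", "saddle", "unstable",
    "hopf_marginal", "saddle_node_marginal",
]


@dataclass(frozen=True)
class MacroState:
    rho_v: float
    psi_v: float
    rho_d: float
    psi_d: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_v, self.psi_v, self.rho_d, self.psi_d], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "MacroState":
        return cls(*(float(v) for v in y))

    def wrapped(self) -> "MacroState":
        """Phases wrapped to (-pi, pi]."""
        def wrap(p: float) -> float:
            w = (-p + math.pi) % (2.0 * math.pi)
            return math.pi - w
        return MacroState(self.rho_v, wrap(self.psi_v), self.rho_d, wrap(self.psi_d))


@dataclass
class Trajectory:
    """Uniformly sampled macroscopic trajectory.

    ``times_h`` is absolute simulation time in hours (the drive phase reference
    is t = 0), strictly increasing with a uniform step.  ``states`` has one row
    per time, columns (rho_v, psi_v, rho_d, psi_d) with phases unwrapped.
    ``frame`` is "rotating" for LD drives and "lab" for DD/LL.
    """

    times_h: np.ndarray
    states: np.ndarray
    frame: Literal["rotating", "lab"]
    drive: DriveSpec
    params: CoreShellParameters
    clip_events: int = 0
    initial_state: tuple[float, float, float, float] = DEFAULT_INITIAL_STATE

    @property
    def rho_v(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def psi_v(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def rho_d(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def psi_d(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def step_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    def final_state(self) -> MacroState:
        return MacroState.from_array(self.states[-1])


@dataclass(frozen=True)
class FixedPointReport:
    state: MacroState
    residual: float
    eigenvalues: np.ndarray
    classification: Classification
    converged: bool
    message: str = ""

    @property
    def stable(self) -> bool:
        return self.converged and self.classification in ("stable_node", "stable_focus")

    @property
    def max_real_eigenvalue(self) -> float:
        return float(np.max(self.eigenvalues.real)) if self.eigenvalues.size else math.nan


@dataclass(frozen=True)
class FreeRunningState:
    """Synchronized free-running (DD/LL) state of the whole SCN.

    The lab-frame dynamics are rotation-invariant, so the synchronized state is
    a fixed point of the reduced relative system (rho_v, rho_d, chi) with
    chi = psi_d - psi_v, rotating rigidly at ``omega`` (dimensionless); its
    period in hours is ``tau_h``.
    """

    rho_v: float
    rho_d: float
    chi: float
    omega: float
    tau_h: float
    eigenvalues: np.ndarray
    classification: Classification
    converged: bool
    message: str = ""

    @property
    def stable(self) -> bool:
        return self.converged and self.classification in ("stable_node", "stable_focus")

    @property
    def max_real_eigenvalue(self) -> float:
        return float(np.max(self.eigenvalues.real)) if self.eigenvalues.size else math.nan


@dataclass(frozen=True)
class BifurcationResult:
    control: str
    critical: float
    label: Literal["hopf_marginal", "saddle_node_marginal"]
    report: FixedPointReport | FreeRunningState
    bracket: tuple[float, float]
    converged: bool
    message: str = ""


# --- right-hand side ---------------------------------------------------------

def _drive_terms(params: CoreShellParameters, drive: DriveSpec) -> tuple[float, float, float]:
    """(omega_F, F_eff, B) in dimensionless units for the given drive."""
    if drive.mode == "LD":
        return params.omega_dimensionless(drive.omega_F_h), params.F, 0.0
    if drive.mode == "LL":
        return 0.0, 0.0, drive.B
    return 0.0, 0.0, 0.0


def macro_rhs(y: Sequence[float], params: CoreShellParameters, drive: DriveSpec) -> np.ndarray:
    """Time derivative of (rho_v, psi_v, rho_d, psi_d), dimensionless time."""
    d = params.dimensionless
    omega_F, F, B = _drive_terms(params, drive)
    return _rhs_core(
        np.asarray(y, dtype=float),
        d.omega_v + B, d.omega_d, d.delta_v, d.delta_d,
        params.K_vv, params.K_dd, params.K_vd, params.K_dv,
        F, omega_F,
    )


def _rhs_core(y, w_v, w_d, delta_v, delta_d, K_vv, K_dd, K_vd, K_dv, F, omega_F):
    rho_v, psi_v, rho_d, psi_d = y
    rv = max(rho_v, RHO_FLOOR)
    rd = max(rho_d, RHO_FLOOR)
    s = math.sin(psi_d - psi_v)
    c = math.cos(psi_d - psi_v)
    Om_v = omega_F - w_v
    Om_d = omega_F - w_d
    drho_v = (
        -rho_v * delta_v
        + 0.5 * K_vv * rho_v * (1.0 - rho_v**2)
        + 0.5 * F * (1.0 - rho_v**2) * math.cos(psi_v)
        + 0.5 * K_dv * rho_d * (1.0 - rho_v**2) * c
    )
    dpsi_v = (
        -Om_v
        - 0.5 * F * (1.0 + rho_v**2) / rv * math.sin(psi_v)
        + 0.5 * K_dv * rho_d * (1.0 + rho_v**2) / rv * s
    )
    drho_d = (
        -rho_d * delta_d
        + 0.5 * K_dd * rho_d * (1.0 - rho_d**2)
        + 0.5 * K_vd * rho_v * (1.0 - rho_d**2) * c
    )
    dpsi_d = -Om_d - 0.5 * K_vd * rho_v * (1.0 + rho_d**2) / rd * s
    return np.array([drho_v, dpsi_v, drho_d, dpsi_d])


def macro_jacobian(y: Sequence[float], params: CoreShellParameters, drive: DriveSpec) -> np.ndarray:
    """Analytic Jacobian of :func:`macro_rhs` with respect to the state."""
    d = params.dimensionless
    omega_F, F, B = _drive_terms(params, drive)
    K_vv, K_dd, K_vd, K_dv = params.K_vv, params.K_dd, params.K_vd, params.K_dv
    rho_v, psi_v, rho_d, psi_d = (float(v) for v in y)
    rv = max(rho_v, RHO_FLOOR)
    rd = max(rho_d, RHO_FLOOR)
    s = math.sin(psi_d - psi_v)
    c = math.cos(psi_d - psi_v)
    sv, cv = math.sin(psi_v), math.cos(psi_v)
    g = (1.0 + rv**2) / rv          # rho_v + 1/rho_v
    dg = 1.0 - 1.0 / rv**2
    h = (1.0 + rd**2) / rd
    dh = 1.0 - 1.0 / rd**2

    J = np.empty((4, 4))
    # d(drho_v)/d*
    J[0, 0] = -d.delta_v + 0.5 * K_vv * (1.0 - 3.0 * rho_v**2) - F * rho_v * cv \
        - K_dv * rho_d * rho_v * c
    J[0, 1] = -0.5 * F * (1.0 - rho_v**2) * sv + 0.5 * K_dv * rho_d * (1.0 - rho_v**2) * s
    J[0, 2] = 0.5 * K_dv * (1.0 - rho_v**2) * c
    J[0, 3] = -0.5 * K_dv * rho_d * (1.0 - rho_v**2) * s
    # d(dpsi_v)/d*
    J[1, 0] = -0.5 * F * sv * dg + 0.5 * K_dv * rho_d * s * dg
    J[1, 1] = -0.5 * F * g * cv - 0.5 * K_dv * rho_d * g * c
    J[1, 2] = 0.5 * K_dv * g * s
    J[1, 3] = 0.5 * K_dv * rho_d * g * c
    # d(drho_d)/d*
    J[2, 0] = 0.5 * K_vd * (1.0 - rho_d**2) * c
    J[2, 1] = 0.5 * K_vd * rho_v * (1.0 - rho_d**2) * s
    J[2, 2] = -d.delta_d + 0.5 * K_dd * (1.0 - 3.0 * rho_d**2) - K_vd * rho_v * rho_d * c
    J[2, 3] = -0.5 * K_vd * rho_v * (1.0 - rho_d**2) * s
    # d(dpsi_d)/d*
    J[3, 0] = -0.5 * K_vd * h * s
    J[3, 1] = 0.5 * K_vd * rho_v * h * c
    J[3, 2] = -0.5 * K_vd * rho_v * s * dh
    J[3, 3] = -0.5 * K_vd * rho_v * h * c
    return J


# --- integration -------------------------------------------------------------

class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_time_h: float):
        super().__init__(f"{message} (last valid time {last_time_h:.3f} h)")
        self.last_time_h = last_time_h


def integrate(
    params: CoreShellParameters,
    drive: DriveSpec,
    *,
    duration_h: float,
    step_h: float = 0.25,
    transient_h: float = 0.0,
    initial: MacroState | Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the macroscopic equations and resample on a uniform grid.

    The trajectory is recorded from ``transient_h`` to ``transient_h +
    duration_h`` with spacing ``step_h`` (hours).  Integration is adaptive
    (DOP853) with dense output; ``rho`` is clipped to [0, 1] only within
    floating tolerance and the number of clipped samples is reported.
    """
    if not (duration_h > 0 and step_h > 0):
        raise ValueError("duration_h and step_h must be positive")
    if initial is None:
        y0 = np.array(DEFAULT_INITIAL_STATE)
    elif isinstance(initial, MacroState):
        y0 = initial.as_array()
    else:
        y0 = np.asarray(initial, dtype=float)

    u = params.frequency_unit
    t_end = (transient_h + duration_h) * u
    fun = lambda t, y: macro_rhs(y, params, drive)  # noqa: E731 — autonomous
    sol = solve_ivp(fun, (0.0, t_end), y0, method="DOP853",
                    rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) / u)

    n = int(math.floor(duration_h / step_h)) + 1
    times_h = transient_h + step_h * np.arange(n)
    ys = sol.sol(times_h * u).T  # (n, 4)

    clip = int(np.sum((ys[:, [0, 2]] < 0.0) | (ys[:, [0, 2]] > 1.0)))
    ys[:, [0, 2]] = np.clip(ys[:, [0, 2]], 0.0, 1.0)

    frame = "rotating" if drive.mode == "LD" else "lab"
    return Trajectory(times_h=times_h, states=ys, frame=frame, drive=drive,
                      params=params, clip_events=clip,
                      initial_state=tuple(float(v) for v in y0))


# --- fixed points and stability ----------------------------------------------

def classify_eigenvalues(eigs: np.ndarray, tol: float = 1e-6) -> Classification:
    """Decision table mapping Jacobian eigenvalues to a stability label.

    - all real parts < -tol: ``stable_node`` (all eigenvalues real) or
      ``stable_focus`` (a complex pair present);
    - leading real part within +-tol of 0: ``hopf_marginal`` if the leading
      eigenvalue has a nonzero imaginary part, else ``saddle_node_marginal``;
    - leading real part > tol: ``saddle`` if some eigenvalue has real part
      < -tol and the leading one is real, else ``unstable``.
    """
    eigs = np.asarray(eigs)
    order = np.argsort(eigs.real)[::-1]
    leading = eigs[order[0]]
    max_re = float(leading.real)
    if max_re < -tol:
        return "stable_focus" if np.any(np.abs(eigs.imag) > tol) else "stable_node"
    if abs(max_re) <= tol:
        return "hopf_marginal" if abs(leading.imag) > tol else "saddle_node_marginal"
    if np.any(eigs.real < -tol) and abs(leading.imag) <= tol:
        return "saddle"
    return "unstable"


def find_fixed_point(
    params: CoreShellParameters,
    drive: DriveSpec,
    guess: MacroState | Sequence[float] | None = None,
    *,
    rotation_h: float = 0.0,
    residual_tol: float = 1e-10,
) -> FixedPointReport:
    """Solve for a stationary state of the macroscopic equations.

    Under LD the equations are already in the rotating frame and a fixed point
    is an entrained state.  Under DD/LL a ``rotation_h`` (rad/h) may be given
    to look for a state rotating rigidly at that trial frequency (see
    :func:`free_running_state` for the self-consistent version).
    """
    if guess is None:
        g = np.array(DEFAULT_INITIAL_STATE)
    elif isinstance(guess, MacroState):
        g = guess.as_array()
    else:
        g = np.asarray(guess, dtype=float)

    w = params.omega_dimensionless(rotation_h) if rotation_h else 0.0
    offset = np.array([0.0, w, 0.0, w])

    sol = root(lambda y: macro_rhs(y, params, drive) - offset, g,
               jac=lambda y: macro_jacobian(y, params, drive),
               method="hybr", tol=1e-13)
    y = sol.x
    res = float(np.max(np.abs(macro_rhs(y, params, drive) - offset)))
    # judge convergence by the residual itself: hybr's progress heuristic can
    # report failure after converging in very few steps from a good guess
    ok = res < residual_tol and 0.0 < y[0] <= 1.0 + 1e-9 and 0.0 < y[2] <= 1.0 + 1e-9
    eigs = np.linalg.eigvals(macro_jacobian(y, params, drive))
    label = classify_eigenvalues(eigs)
    msg = "" if ok else (sol.message if not sol.success else
                         f"residual {res:.2e} or state out of range")
    return FixedPointReport(state=MacroState.from_array(y), residual=res,
                            eigenvalues=eigs, classification=label,
                            converged=ok, message=msg)


_REL_GUESS = np.array([0.8, 0.4, 0.3])


def _relative_rhs(y: np.ndarray, params: CoreShellParameters, B: float) -> np.ndarray:
    """Autonomous (rho_v, rho_d, chi) system for DD/LL; chi = psi_d - psi_v."""
    d = params.dimensionless
    rho_v, rho_d, chi = y
    rv = max(rho_v, RHO_FLOOR)
    rd = max(rho_d, RHO_FLOOR)
    s, c = math.sin(chi), math.cos(chi)
    drho_v = -rho_v * d.delta_v + 0.5 * params.K_vv * rho_v * (1 - rho_v**2) \
        + 0.5 * params.K_dv * rho_d * (1 - rho_v**2) * c
    drho_d = -rho_d * d.delta_d + 0.5 * params.K_dd * rho_d * (1 - rho_d**2) \
        + 0.5 * params.K_vd * rho_v * (1 - rho_d**2) * c
    dchi = (d.omega_d - d.omega_v - B) - (
        0.5 * params.K_vd * rho_v * (1 + rho_d**2) / rd
        + 0.5 * params.K_dv * rho_d * (1 + rho_v**2) / rv
    ) * s
    return np.array([drho_v, drho_d, dchi])


def free_running_state(
    params: CoreShellParameters,
    B: float = 0.0,
    guess: Sequence[float] | None = None,
) -> FreeRunningState:
    """Synchronized free-running state under DD (B = 0) or LL (B != 0).

    Solves the relative system (rho_v, rho_d, chi) for a fixed point and
    recovers the rigid rotation rate ``omega`` from the core phase equation;
    stability is judged from the 3x3 Jacobian of the relative system (a Hopf
    instability of this system is the onset of a dissociated rhythm).
    """
    g = np.asarray(guess, dtype=float) if guess is not None else _REL_GUESS
    sol = root(lambda y: _relative_rhs(y, params, B), g, method="hybr", tol=1e-13)
    y = sol.x
    res = float(np.max(np.abs(_relative_rhs(y, params, B))))
    ok = res < 1e-9 and 0 < y[0] <= 1 + 1e-9 and 0 < y[1] <= 1 + 1e-9

    # central finite differences on the smooth relative system
    J = np.empty((3, 3))
    h = 1e-7
    for j in range(3):
        yp = y.copy(); yp[j] += h
        ym = y.copy(); ym[j] -= h
        J[:, j] = (_relative_rhs(yp, params, B) - _relative_rhs(ym, params, B)) / (2 * h)
    eigs = np.linalg.eigvals(J)
    label = classify_eigenvalues(eigs)

    d = params.dimensionless
    rho_v, rho_d, chi = y
    omega = (d.omega_v + B) + 0.5 * params.K_dv * rho_d * (1 + rho_v**2) \
        / max(rho_v, RHO_FLOOR) * math.sin(chi)
    tau_h = 2 * math.pi / (omega * params.frequency_unit) if omega > 0 else math.inf
    return FreeRunningState(rho_v=float(rho_v), rho_d=float(rho_d), chi=float(chi),
                            omega=float(omega), tau_h=float(tau_h),
                            eigenvalues=eigs, classification=label, converged=ok,
                            message="" if ok else sol.message)


def classify_bifurcation(
    params: CoreShellParameters,
    *,
    control: Literal["T", "B"],
    bracket: tuple[float, float],
    tol: float = 0.005,
    guess: Sequence[float] | None = None,
) -> BifurcationResult:
    """Locate and label the loss of stability of the tracked steady state.

    ``bracket = (stable_end, unstable_end)`` in hours (control "T", the LD
    entrained fixed point) or in dimensionless intensity (control "B", the LL
    synchronized state).  Bisection on the leading eigenvalue's real part with
    continuation of the steady state from the stable end; the label is
    ``hopf_marginal`` if the leading pair is complex at the crossing,
    ``saddle_node_marginal`` if it is real (or the state ceases to exist).
    """
    stable_end, unstable_end = bracket

    def probe_T(T, g):
        r = find_fixed_point(params, DriveSpec(mode="LD", T=T), guess=g)
        return r, (r.state.as_array() if r.converged else None)

    def probe_B(B, g):
        r = free_running_state(params, B=B, guess=g)
        return r, (np.array([r.rho_v, r.rho_d, r.chi]) if r.converged else None)

    probe = probe_T if control == "T" else probe_B
    r0, g = probe(stable_end, guess)
    if not (r0.converged and r0.stable) and guess is None:
        # root search from the default state missed the attractor: integrate
        # onto it first, then retry
        if control == "T":
            drive = DriveSpec(mode="LD", T=stable_end)
            settle = integrate(params, drive, duration_h=stable_end,
                               transient_h=100 * stable_end, step_h=stable_end)
            r0, g = probe(stable_end, settle.states[-1])
        else:
            drive = DriveSpec(mode="LL", B=stable_end) if stable_end else DriveSpec(mode="DD")
            settle = integrate(params, drive, duration_h=24.0,
                               transient_h=2400.0, step_h=24.0)
            y = settle.states[-1]
            r0, g = probe(stable_end, np.array([y[0], y[2], y[3] - y[1]]))
    if not (r0.converged and r0.stable):
        return BifurcationResult(control=control, critical=math.nan, label="hopf_marginal",
                                 report=r0, bracket=bracket, converged=False,
                                 message="no stable steady state at the stable end of the bracket")
    r1, _ = probe(unstable_end, g)
    if r1.converged and r1.stable:
        return BifurcationResult(control=control, critical=math.nan, label="hopf_marginal",
                                 report=r1, bracket=bracket, converged=False,
                                 message="no stability change inside the bracket")

    lo, hi = stable_end, unstable_end
    last_stable = r0
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        r, gm = probe(mid, g)
        if r.converged and r.stable:
            lo, g, last_stable = mid, gm, r
        else:
            hi = mid
    eigs = last_stable.eigenvalues
    leading = eigs[np.argmax(eigs.real)]
    label = "hopf_marginal" if abs(leading.imag) > 1e-6 else "saddle_node_marginal"
    return BifurcationResult(control=control, critical=0.5 * (lo + hi), label=label,
                             report=last_stable, bracket=bracket, converged=True)
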
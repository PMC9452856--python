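"""Model parameters, unit conversions and the coupling <-> synchrony calibration.

The model describes the suprachiasmatic nucleus (SCN) as two all-to-all coupled
populations of Kuramoto phase oscillators: the retinorecipient ventral *core*
and the dorsal *shell*.  Each population is summarised by the mean free-running
period ``tau`` (hours) and the spread ``sigma`` (hours, SD of free-running
periods); natural frequencies follow a Cauchy-Lorentz law whose half width at
half maximum is ``Delta = 2*pi*sigma/tau**2`` (rad/h), the small-spread
conversion of a period SD into a frequency SD.

All dynamical computations are done in dimensionless form: frequencies are
divided by the core spread ``Delta_v`` (so the dimensionless core spread is 1
by construction) and time is multiplied by it.  One dimensionless time unit is
``1/Delta_v`` hours (about 77.1 h for the default mouse calibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple

__all__ = [
    "GroupParameters",
    "CoreShellParameters",
    "DriveSpec",
    "DimensionlessSet",
    "nondimensionalize",
    "intracoupling_from_sync",
    "sync_from_intracoupling",
    "critical_intracoupling",
    "table1",
    "PRESETS",
]


class ParameterError(ValueError):
    """Invalid model parameter."""


@dataclass(frozen=True)
class GroupParameters:
    """One oscillator population, in dimensional (hour) units.

    Attributes
    ----------
    tau : float
        Mean free-running period, hours.  Must be positive.
    sigma : float
        Standard deviation of free-running periods, hours.  Must be positive.
    """

    tau: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ParameterError(f"mean period tau must be positive, got {self.tau}")
        if not (self.sigma > 0):
            raise ParameterError(f"period spread sigma must be positive, got {self.sigma}")

    @property
    def omega_bar(self) -> float:
        """Mean free-running angular frequency, rad/h (= 2*pi/tau)."""
        return 2.0 * math.pi / self.tau

    @property
    def spread(self) -> float:
        """Lorentzian half width at half maximum of the frequency law, rad/h.

        Identified with the frequency SD ``2*pi*sigma/tau**2`` obtained by
        propagating the period SD through ``omega = 2*pi/tau``.
        """
        return 2.0 * math.pi * self.sigma / self.tau**2


class DimensionlessSet(NamedTuple):
    """Dimensionless group parameters (frequencies in units of the core spread)."""

    omega_v: float
    omega_d: float
    delta_v: float
    delta_d: float


@dataclass(frozen=True)
class CoreShellParameters:
    """The nine-parameter core-shell model.

    ``core``/``shell`` are dimensional; the couplings ``K_vv`` (within core),
    ``K_dd`` (within shell), ``K_vd`` (core onto shell), ``K_dv`` (shell onto
    core) and the light-cue strength ``F`` are dimensionless, already expressed
    in units of the core spread.  ``frequency_unit`` is the dimensional value
    (rad/h) of the core spread used to nondimensionalize.
    """

    core: GroupParameters
    shell: GroupParameters
    K_vv: float
    K_dd: float
    K_vd: float
    K_dv: float
    F: float
    frequency_unit: float = field(default=0.0)

    def __post_init__(self) -> None:
        unit = self.frequency_unit or self.core.spread
        object.__setattr__(self, "frequency_unit", unit)
        if not (self.frequency_unit > 0):
            raise ParameterError("frequency_unit must be positive")
        for name in ("K_vv", "K_dd", "K_vd", "K_dv", "F"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"coupling {name} must be finite, got {v}")
        if self.F < 0:
            raise ParameterError(f"cue strength F must be >= 0, got {self.F}")

    # --- dimensionless view -------------------------------------------------
    @property
    def dimensionless(self) -> DimensionlessSet:
        u = self.frequency_unit
        return DimensionlessSet(
            omega_v=self.core.omega_bar / u,
            omega_d=self.shell.omega_bar / u,
            delta_v=self.core.spread / u,
            delta_d=self.shell.spread / u,
        )

    @property
    def time_unit_h(self) -> float:
        """Hours per dimensionless time unit (1/frequency_unit)."""
        return 1.0 / self.frequency_unit

    def hours_to_dimensionless(self, t_h: float) -> float:
        return t_h * self.frequency_unit

    def dimensionless_to_hours(self, t: float) -> float:
        return t / self.frequency_unit

    def omega_dimensionless(self, omega_rad_per_h: float) -> float:
        return omega_rad_per_h / self.frequency_unit

    def with_shell_period(self, tau_d: float) -> "CoreShellParameters":
        """Same model with the shell mean period replaced (entrainment-range scans)."""
        return replace(self, shell=GroupParameters(tau=tau_d, sigma=self.shell.sigma))


@dataclass(frozen=True)
class DriveSpec:
    """Lighting protocol.

    ``LD``: sinusoidal cue of period ``T`` hours and strength ``F`` acting on
    the core; the cue phase is 0 (it provides the reference time).
    ``DD``: constant darkness, the cue term is off.
    ``LL``: constant light of signed dimensionless intensity ``B``, modelled as
    a shift of the core mean frequency (cue term off).
    """

    mode: Literal["LD", "DD", "LL"]
    T: float | None = None
    B: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.mode == "LD":
            if self.T is None or not (self.T > 0):
                raise ParameterError("LD drive requires a positive period T (hours)")
        elif self.mode == "DD":
            if self.T is not None:
                raise ParameterError("DD drive takes no period T")
        elif self.mode == "LL":
            if self.T is not None:
                raise ParameterError("LL drive takes no period T")
            if not math.isfinite(self.B):
                raise ParameterError("LL drive requires finite B")
        else:
            raise ParameterError(f"unknown drive mode {self.mode!r}")
        if self.phi != 0.0:
            raise ParameterError("the cue phase is fixed at 0 (reference time)")

    @property
    def omega_F_h(self) -> float:
        """Drive angular frequency in rad/h (0 for DD/LL: lab frame)."""
        return 2.0 * math.pi / self.T if self.mode == "LD" else 0.0

    @property
    def field_on(self) -> bool:
        return self.mode == "LD"


# --- operations --------------------------------------------------------------

def nondimensionalize(
    core: GroupParameters,
    shell: GroupParameters,
    *,
    K_vv: float,
    K_dd: float,
    K_vd: float,
    K_dv: float,
    F: float,
) -> CoreShellParameters:
    """Build the full parameter set, taking the core spread as frequency unit.

    The couplings and cue strength are taken as already dimensionless (the
    model's calibration is stated in units of the core spread).
    """
    return CoreShellParameters(
        core=core, shell=shell, K_vv=K_vv, K_dd=K_dd, K_vd=K_vd, K_dv=K_dv, F=F,
        frequency_unit=core.spread,
    )


def intracoupling_from_sync(rho: float, delta: float) -> float:
    """Intracoupling that sustains synchronization index ``rho`` in an isolated
    group of spread ``delta``: ``K = 2*delta/(1 - rho**2)``."""
    if not (0.0 <= rho < 1.0):
        raise ParameterError(f"synchronization index must be in [0, 1), got {rho}")
    if not (delta > 0):
        raise ParameterError(f"spread must be positive, got {delta}")
    return 2.0 * delta / (1.0 - rho**2)


def sync_from_intracoupling(K: float, delta: float) -> float:
    """Stationary synchronization index of an isolated group:
    ``sqrt(1 - 2*delta/K)`` above the critical coupling, else 0 (incoherent)."""
    if not (K > 0):
        raise ParameterError(f"intracoupling must be positive, got {K}")
    if not (delta > 0):
        raise ParameterError(f"spread must be positive, got {delta}")
    if K <= 2.0 * delta:
        return 0.0
    return math.sqrt(1.0 - 2.0 * delta / K)


def critical_intracoupling(delta: float) -> float:
    """Critical intracoupling ``2*delta`` at which synchronization emerges."""
    if not (delta > 0):
        raise ParameterError(f"spread must be positive, got {delta}")
    return 2.0 * delta


# --- presets -----------------------------------------------------------------

def table1(column: str = "model") -> CoreShellParameters:
    """The packaged mouse calibration.

    ``"model"`` is the default working parameter set (shell period 23.3 h,
    tuned so the entrained shell leads the core by 2.3 h at T = 24 h);
    ``"reference"`` keeps the literature shell period 23.9 h.
    """
    if column not in ("model", "reference"):
        raise ParameterError(f"unknown preset column {column!r}")
    tau_d = 23.3 if column == "model" else 23.9
    return nondimensionalize(
        GroupParameters(tau=25.1, sigma=1.3),
        GroupParameters(tau=tau_d, sigma=1.9),
        K_vv=5.6, K_dd=4.0, K_vd=1.1, K_dv=0.5, F=1.5,
    )


PRESETS = {
    "table1": lambda: table1("model"),
    "table1-reference": lambda: table1("reference"),
}
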
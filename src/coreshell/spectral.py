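"""Spectral decomposition of the lab-frame SCN activity proxy.

The observable is the real part of a group's complex order parameter.  In the
rotating frame of an LD drive this is ``rho(t)*cos(omega_F*t + psi(t))``;
under DD/LL the trajectory is already in the lab frame and the observable is
``rho(t)*cos(psi(t))``.  An entrained (or synchronized free-running) state
contributes a single spectral line; dissociation shows up as additional
independent components.

Intensities are lobe-integrated periodogram power with the taper's power
normalization, so the total over all components approximates the series
variance (Parseval) and a pure cosine of amplitude A has intensity A**2/2.
The absolute normalization is only meaningful in ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .reduced_model import Trajectory

__all__ = [
    "SpectralComponent",
    "lab_observable",
    "spectral_components",
    "second_rhythm",
    "drift_rate_period",
    "FIELD_LOCK_TOL_H",
    "SECOND_RHYTHM_FLOOR",
]

#: |period - T| below which a component counts as locked to the drive, hours.
FIELD_LOCK_TOL_H = 0.05

#: Second-rhythm intensity floor, relative to the dominant component.
SECOND_RHYTHM_FLOOR = 0.01


@dataclass(frozen=True)
class SpectralComponent:
    group: Literal["core", "shell"]
    period_h: float
    intensity: float
    field_locked: bool


def lab_observable(traj: Trajectory, group: Literal["core", "shell"]) -> np.ndarray:
    """Lab-frame activity proxy Re(z) for one group, on the trajectory grid."""
    if group not in ("core", "shell"):
        raise ValueError(f"group must be 'core' or 'shell', got {group!r}")
    dt = np.diff(traj.times_h)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9 * dt[0]):
        raise ValueError("trajectory grid is not uniform")
    rho = traj.rho_v if group == "core" else traj.rho_d
    psi = traj.psi_v if group == "core" else traj.psi_d
    if traj.frame == "rotating":
        return rho * np.cos(traj.drive.omega_F_h * traj.times_h + psi)
    return rho * np.cos(psi)


def _periodogram(x: np.ndarray, dt_h: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered periodogram normalized so that sum(P) ~ var(x)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    w = np.hanning(n)
    X = np.fft.rfft((x - x.mean()) * w)
    P = np.abs(X) ** 2 * (2.0 / (n * np.sum(w**2)))
    P[0] *= 0.5
    if n % 2 == 0:
        P[-1] *= 0.5
    f = np.fft.rfftfreq(n, dt_h)
    return f, P


def spectral_components(
    series: np.ndarray,
    dt_h: float,
    *,
    group: Literal["core", "shell"] = "core",
    drive_period_h: float | None = None,
    floor: float = 1e-6,
    min_period_h: float = 1.0,
    min_cycles: float = 64.0,
) -> list[SpectralComponent]:
    """Independent rhythm components of a uniformly sampled observable.

    Local maxima of the tapered periodogram above ``floor`` (relative to the
    strongest peak) are returned as components, strongest first.  Peak periods
    are refined by quadratic interpolation of the log-power through the three
    bins around the maximum; intensities integrate the power over the peak's
    lobe (between the adjacent local minima).

    ``min_cycles`` guards against records too short to resolve neighbouring
    circadian lines: the series must span at least that many cycles of
    ``drive_period_h`` (when given).
    """
    series = np.asarray(series, dtype=float)
    span_h = series.size * dt_h
    if drive_period_h is not None and span_h < min_cycles * drive_period_h:
        raise ValueError(
            f"series spans {span_h:.0f} h but at least "
            f"{min_cycles * drive_period_h:.0f} h (= {min_cycles:g} drive periods) "
            "are required for component separation"
        )
    f, P = _periodogram(series, dt_h)
    if P.max() <= 0:
        return []
    df = f[1] - f[0]
    out: list[tuple[float, float]] = []
    for k in range(2, P.size - 1):
        if not (P[k] > P[k - 1] and P[k] >= P[k + 1]):
            continue
        if P[k] < floor * P.max():
            continue
        if f[k] > 1.0 / min_period_h:
            continue
        # quadratic interpolation of log-power around the maximum
        la, lb, lc = math.log(P[k - 1]), math.log(P[k]), math.log(P[k + 1])
        denom = la - 2.0 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        fk = f[k] + delta * df
        # integrate the lobe between neighbouring local minima
        lo = k
        while lo > 1 and P[lo - 1] < P[lo]:
            lo -= 1
        hi = k
        while hi < P.size - 1 and P[hi + 1] < P[hi]:
            hi += 1
        out.append((1.0 / fk, float(P[lo:hi + 1].sum())))
    out.sort(key=lambda t: -t[1])
    return [
        SpectralComponent(
            group=group, period_h=p, intensity=i,
            field_locked=(drive_period_h is not None
                          and abs(p - drive_period_h) < FIELD_LOCK_TOL_H),
        )
        for p, i in out
    ]


def second_rhythm(
    components: list[SpectralComponent],
    drive_period_h: float,
    floor: float = SECOND_RHYTHM_FLOOR,
) -> SpectralComponent | None:
    """Strongest non-drive-locked component above ``floor`` x dominant intensity.

    Returns None inside the entrainment range (single locked line).
    """
    if not components:
        return None
    top = components[0].intensity
    for comp in components:
        if comp.field_locked:
            continue
        if abs(comp.period_h - drive_period_h) < FIELD_LOCK_TOL_H:
            continue
        if comp.intensity >= floor * top:
            return comp
    return None


def drift_rate_period(
    traj: Trajectory,
    group: Literal["core", "shell"],
    *,
    min_drift_rad_per_h: float = 1e-4,
) -> float | None:
    """Second-rhythm period from the mean phase drift rate, hours.

    A least-squares line is fit to the unwrapped group phase.  In the rotating
    frame the lab-frame rhythm frequency is ``omega_F + <dpsi/dt>``; under
    DD/LL it is ``|<dpsi/dt>|``.  Returns None when the drift is below
    ``min_drift_rad_per_h`` in a rotating frame (entrained: the rhythm sits at
    the drive period itself).
    """
    psi = traj.psi_v if group == "core" else traj.psi_d
    psi = np.unwrap(psi)
    slope = np.polyfit(traj.times_h, psi, 1)[0]  # rad/h
    if traj.frame == "rotating":
        if abs(slope) < min_drift_rad_per_h:
            return None
        w = traj.drive.omega_F_h + slope
    else:
        w = abs(slope)
    if w <= 0:
        return None
    return 2.0 * math.pi / w
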
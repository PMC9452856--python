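"""Configuration files, result serialization and deterministic fixtures.

Results are small time series and tables, so everything is written as
diff-able text: CSV with an explicit header plus a JSON sidecar (same path
with ``.json`` appended) carrying parameters, drive, seeds, solver options and
the package version — enough to reproduce the file bit-for-bit on the same
platform.
"""

from __future__ import annotations

import dataclasses
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .parameters import (
    CoreShellParameters,
    DriveSpec,
    GroupParameters,
    PRESETS,
    intracoupling_from_sync,
    nondimensionalize,
)
from .reduced_model import Trajectory

__all__ = [
    "ConfigError",
    "load_config",
    "parameters_to_dict",
    "drive_to_dict",
    "RunRecord",
    "write_trajectory",
    "read_trajectory_csv",
    "component_seed",
    "generate_fixtures",
]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


_GROUP_KEYS = {"tau_h", "sigma_h"}
_COUPLING_KEYS = {"K_vv", "K_dd", "K_vd", "K_dv", "F", "sync_v", "sync_d"}
_DRIVE_KEYS = {"mode", "T_h", "B"}
_TOP_KEYS = {"core", "shell", "couplings", "drive"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{where}'; "
                          f"allowed: {sorted(allowed)}")


def _require(section: dict, key: str, where: str) -> Any:
    if key not in section:
        raise ConfigError(f"missing required key '{key}' in section '{where}'")
    return section[key]


def _group_from(section: dict, where: str) -> GroupParameters:
    _check_keys(section, _GROUP_KEYS, where)
    tau = _require(section, "tau_h", where)
    sigma = _require(section, "sigma_h", where)
    for name, v in (("tau_h", tau), ("sigma_h", sigma)):
        if not isinstance(v, (int, float)) or not v > 0:
            raise ConfigError(f"'{name}' in '{where}' must be a positive number, got {v!r}")
    return GroupParameters(tau=float(tau), sigma=float(sigma))


def load_config(path: str | Path) -> tuple[CoreShellParameters, DriveSpec, dict]:
    """Read a YAML model configuration.

    Schema (all couplings dimensionless)::

        core:      {tau_h: 25.1, sigma_h: 1.3}
        shell:     {tau_h: 23.3, sigma_h: 1.9}
        couplings: {K_vv: 5.6, K_dd: 4.0, K_vd: 1.1, K_dv: 0.5, F: 1.5}
        drive:     {mode: LD, T_h: 24.0}   # or {mode: DD} / {mode: LL, B: -0.2}

    Instead of ``K_vv``/``K_dd`` the intracouplings may be requested through
    target synchronization indices ``sync_v``/``sync_d`` of the isolated
    groups; the coupling-synchrony calibration is then applied and reported in
    the returned notes dict.  Unknown keys are rejected by name.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    _check_keys(raw, _TOP_KEYS, "<top level>")
    for sec in ("core", "shell", "couplings", "drive"):
        if sec not in raw:
            raise ConfigError(f"missing required section '{sec}'")

    core = _group_from(raw["core"], "core")
    shell = _group_from(raw["shell"], "shell")

    cpl = raw["couplings"]
    _check_keys(cpl, _COUPLING_KEYS, "couplings")
    notes: dict[str, Any] = {}
    unit = core.spread
    if "sync_v" in cpl or "sync_d" in cpl:
        if "K_vv" in cpl or "K_dd" in cpl:
            raise ConfigError("give either sync_v/sync_d or K_vv/K_dd, not both")
        sync_v = float(_require(cpl, "sync_v", "couplings"))
        sync_d = float(_require(cpl, "sync_d", "couplings"))
        K_vv = intracoupling_from_sync(sync_v, core.spread / unit)
        K_dd = intracoupling_from_sync(sync_d, shell.spread / unit)
        notes["calibration"] = {
            "sync_v": sync_v, "sync_d": sync_d,
            "K_vv": K_vv, "K_dd": K_dd,
        }
    else:
        K_vv = float(_require(cpl, "K_vv", "couplings"))
        K_dd = float(_require(cpl, "K_dd", "couplings"))
    params = nondimensionalize(
        core, shell,
        K_vv=K_vv, K_dd=K_dd,
        K_vd=float(_require(cpl, "K_vd", "couplings")),
        K_dv=float(_require(cpl, "K_dv", "couplings")),
        F=float(_require(cpl, "F", "couplings")),
    )

    drv = raw["drive"]
    _check_keys(drv, _DRIVE_KEYS, "drive")
    mode = _require(drv, "mode", "drive")
    if mode == "LD":
        drive = DriveSpec(mode="LD", T=float(_require(drv, "T_h", "drive")))
    elif mode == "DD":
        drive = DriveSpec(mode="DD")
    elif mode == "LL":
        drive = DriveSpec(mode="LL", B=float(drv.get("B", 0.0)))
    else:
        raise ConfigError(f"drive mode must be LD, DD or LL, got {mode!r}")
    return params, drive, notes


def parameters_to_dict(params: CoreShellParameters) -> dict:
    d = params.dimensionless
    return {
        "core": {"tau_h": params.core.tau, "sigma_h": params.core.sigma},
        "shell": {"tau_h": params.shell.tau, "sigma_h": params.shell.sigma},
        "couplings": {"K_vv": params.K_vv, "K_dd": params.K_dd,
                      "K_vd": params.K_vd, "K_dv": params.K_dv, "F": params.F},
        "dimensionless": {"omega_v": d.omega_v, "omega_d": d.omega_d,
                          "delta_v": d.delta_v, "delta_d": d.delta_d},
        "frequency_unit_rad_per_h": params.frequency_unit,
    }


def drive_to_dict(drive: DriveSpec) -> dict:
    out: dict[str, Any] = {"mode": drive.mode}
    if drive.mode == "LD":
        out["T_h"] = drive.T
    if drive.mode == "LL":
        out["B"] = drive.B
    return out


@dataclasses.dataclass
class RunRecord:
    """Sidecar metadata sufficient to reproduce a result file."""

    command: str
    params: dict
    drive: dict | None = None
    seed: int | None = None
    options: dict = dataclasses.field(default_factory=dict)
    checks: dict = dataclasses.field(default_factory=dict)
    version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, csv_path: str | Path) -> Path:
        sidecar = Path(str(csv_path) + ".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                      default=_json_default) + "\n")
        return sidecar


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_trajectory(traj: Trajectory, path: str | Path, *,
                     command: str = "simulate", seed: int | None = None,
                     options: dict | None = None) -> Path:
    """Trajectory CSV (time_h, rho_v, psi_v, rho_d, psi_d, frame) + sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "time_h": traj.times_h,
        "rho_v": traj.rho_v, "psi_v": traj.psi_v,
        "rho_d": traj.rho_d, "psi_d": traj.psi_d,
    })
    df["frame"] = traj.frame
    df.to_csv(path, index=False, float_format="%.12g")
    record = RunRecord(
        command=command,
        params=parameters_to_dict(traj.params),
        drive=drive_to_dict(traj.drive),
        seed=seed,
        options={"step_h": traj.step_h, "initial_state": list(traj.initial_state),
                 "clip_events": traj.clip_events, **(options or {})},
    )
    record.write(path)
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- seeding -----------------------------------------------------------------

#: Registry mapping a component name to a fixed counter, so that expanding the
#: global seed for one protocol never perturbs another's stream.
_SEED_REGISTRY = {
    "microscopic": 1,
    "fixtures": 2,
    "initial_phases": 3,
}


def component_seed(seed: int, component: str) -> int:
    """Derive a per-component seed from the global one (documented counters)."""
    if component not in _SEED_REGISTRY:
        raise KeyError(f"unknown component {component!r}; "
                       f"known: {sorted(_SEED_REGISTRY)}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_SEED_REGISTRY[component],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# --- fixtures ----------------------------------------------------------------

def generate_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write deterministic test inputs: presets, short trajectories, two-tone.

    Outputs (all seed-stamped through their sidecars):

    - ``preset_table1.yaml``, ``preset_table1_reference.yaml``
    - ``traj_ld24.csv`` — entrained LD trajectory at T = 24 h
    - ``traj_dd.csv`` — constant-darkness trajectory
    - ``traj_ld26.csv`` — dissociated trajectory at T = 26 h
    - ``twotone.csv`` — synthetic two-component series with known periods
    """
    from .protocols import run_drive  # deferred: protocols imports spectral

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    for name, tau_d in (("table1", 23.3), ("table1_reference", 23.9)):
        p = outdir / f"preset_{name}.yaml"
        p.write_text(yaml.safe_dump({
            "core": {"tau_h": 25.1, "sigma_h": 1.3},
            "shell": {"tau_h": tau_d, "sigma_h": 1.9},
            "couplings": {"K_vv": 5.6, "K_dd": 4.0, "K_vd": 1.1,
                          "K_dv": 0.5, "F": 1.5},
            "drive": {"mode": "LD", "T_h": 24.0},
        }, sort_keys=False))
        out[f"preset_{name}"] = p

    params = PRESETS["table1"]()
    runs = {
        "traj_ld24": DriveSpec(mode="LD", T=24.0),
        "traj_dd": DriveSpec(mode="DD"),
        "traj_ld26": DriveSpec(mode="LD", T=26.0),
    }
    for name, drive in runs.items():
        traj = run_drive(params, drive, transient_periods=50, record_periods=70)
        p = outdir / f"{name}.csv"
        write_trajectory(traj, p, command=f"fixtures:{name}", seed=seed)
        out[name] = p

    rng = np.random.default_rng(component_seed(seed, "fixtures"))
    t = np.arange(0.0, 4800.0, 0.25)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
    x = np.cos(2 * np.pi * t / 24.0 + phase1) + 0.3 * np.cos(2 * np.pi * t / 25.3 + phase2)
    p = outdir / "twotone.csv"
    pd.DataFrame({"time_h": t, "x": x}).to_csv(p, index=False, float_format="%.12g")
    RunRecord(command="fixtures:twotone", params={},
              seed=seed, options={"periods_h": [24.0, 25.3],
                                  "amplitudes": [1.0, 0.3],
                                  "phases_rad": [float(phase1), float(phase2)]}
              ).write(p)
    out["twotone"] = p
    return out
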
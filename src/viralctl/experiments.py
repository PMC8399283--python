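"""End-user experiment drivers: preset runs, regime maps, config files.

``run_example`` reproduces the two study conditions at regime level: the
persistence preset (high recruitment, R0* > 1) and the extinction preset
(low recruitment, R0* < 1).  Because the original figures state no seeds,
initial conditions, step sizes or horizons, outputs are a seeded stochastic
trajectory, its deterministic comparator, post-burn-in marginal histograms,
and a regime report — not pixel-matched figures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .longrun import classify_regime, estimate_stationary, lyapunov_exponent_y
from .model import stochastic_reproduction_number
from .params import (
    ModelParams,
    config_keys,
    get_preset,
    params_from_dict,
    params_to_dict,
)
from .simulate import SimConfig, Trajectory, simulate, simulate_deterministic, simulate_ensemble

__all__ = [
    "DEFAULT_HORIZONS",
    "RegimeMap",
    "run_example",
    "regime_map",
    "read_config",
    "write_config",
    "write_outputs",
]

# Horizons long enough for the regime signal to dominate Monte-Carlo noise
# at the preset noise levels: stationary histograms need a long ergodic
# window; extinction needs time for ln y to fall by several units.
DEFAULT_HORIZONS = {"example1": 2000.0, "example2": 3000.0}

_SIM_KEYS = {"dt": float, "t_max": float, "seed": int,
             "record_every": int, "scheme": str, "positivity_policy": str}


def _provenance(params: ModelParams, config: SimConfig) -> str:
    items = [f"viralctl {__version__}", f"seed={config.seed}",
             f"dt={config.dt:g}", f"t_max={config.t_max:g}",
             f"scheme={config.scheme}"]
    items += [f"{k}={v:g}" for k, v in params_to_dict(params).items()]
    return "\n".join(items)


def run_example(name: str, seed: int = 0, t_max: float | None = None,
                out_dir: str | Path = ".") -> dict:
    """Run one preset end to end and write its artifacts.

    Writes, under ``out_dir``:

    * ``<name>_trajectory.csv`` — the stochastic path (t, x, y, z, w);
    * ``<name>_deterministic.csv`` — the noise-free comparator;
    * ``<name>_density.csv`` — post-burn-in marginal histograms
      (component, bin_left, bin_right, mass);
    * ``<name>_report.json`` — regime report plus run metadata.

    Returns a dict with the report and the written paths.  Outputs are
    deterministic given (name, seed, t_max).
    """
    params = get_preset(name)
    horizon = DEFAULT_HORIZONS[name] if t_max is None else float(t_max)
    config = SimConfig(dt=0.01, t_max=horizon, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    traj = simulate(params, config)
    det = simulate_deterministic(params, config)
    regime = classify_regime(params)
    stationary = estimate_stationary(traj, burn_in_fraction=0.2)
    extinction = lyapunov_exponent_y(traj)

    prov = _provenance(params, config)
    paths = {
        "trajectory": out_dir / f"{name}_trajectory.csv",
        "deterministic": out_dir / f"{name}_deterministic.csv",
        "density": out_dir / f"{name}_density.csv",
        "report": out_dir / f"{name}_report.json",
    }
    traj.to_csv(paths["trajectory"], header_comment=prov)
    det.to_csv(paths["deterministic"], header_comment=prov)

    with open(paths["density"], "w") as fh:
        for line in prov.splitlines():
            fh.write(f"# {line}\n")
        fh.write("component,bin_left,bin_right,mass\n")
        for comp, summ in stationary.components.items():
            for left, right, mass in zip(summ.bin_edges[:-1],
                                         summ.bin_edges[1:], summ.masses):
                fh.write("%s,%.17g,%.17g,%.17g\n" % (comp, left, right, mass))

    report = {
        "preset": name,
        "version": __version__,
        "seed": seed,
        "dt": config.dt,
        "t_max": horizon,
        "params": params_to_dict(params),
        "regime": regime.to_dict(),
        "n_positivity_events": traj.n_positivity_events,
        "extinction_diagnostics": extinction.to_dict(),
        "final_state": [float(v) for v in traj.final_state],
    }
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"report": report, "paths": {k: str(v) for k, v in paths.items()},
            "trajectory": traj, "deterministic": det,
            "stationary": stationary}


@dataclass
class RegimeMap:
    """R0* and classification over a two-parameter grid."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    r0_star: np.ndarray             # shape (len(axis1), len(axis2))
    classification: np.ndarray      # same shape, dtype=object
    slope_sign: np.ndarray | None = None  # -1/+1 median ln-y slope sign

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.axis1_values):
            for j, v2 in enumerate(self.axis2_values):
                row = {
                    self.axis1_name: v1,
                    self.axis2_name: v2,
                    "R0_star": self.r0_star[i, j],
                    "classification": self.classification[i, j],
                }
                if self.slope_sign is not None:
                    row["median_lny_slope_sign"] = self.slope_sign[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def regime_map(base: ModelParams, axis1: tuple[str, list[float]],
               axis2: tuple[str, list[float]], confirm: bool = False,
               seed: int = 0, n_reps: int = 5,
               t_max: float = 1000.0) -> RegimeMap:
    """Classify every cell of a two-parameter grid around ``base``.

    Axis names are config keys (lambda, d/h, e, a, p, c, b, sigma,
    sigma1..3).  With ``confirm`` set, a short ensemble per cell records
    the sign of the median trailing ln-y slope as an empirical check of
    the threshold classification.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    base_dict = params_to_dict(base)
    for nm in (name1, name2):
        key = "d" if nm == "h" else nm
        if key not in base_dict:
            raise ValueError(f"invalid axis parameter {nm!r}; valid keys: "
                             + ", ".join(config_keys()))
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    r0s = np.empty((vals1.size, vals2.size))
    cls = np.empty((vals1.size, vals2.size), dtype=object)
    sign = np.zeros_like(r0s) if confirm else None
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            d = dict(base_dict)
            d["d" if name1 == "h" else name1] = float(v1)
            d["d" if name2 == "h" else name2] = float(v2)
            cell = params_from_dict(d)
            report = classify_regime(cell)
            r0s[i, j] = report.R0_star
            cls[i, j] = report.classification
            if confirm:
                config = SimConfig(dt=0.01, t_max=t_max,
                                   seed=seed + 1000 * i + j)
                reps = simulate_ensemble(cell, config, n_reps)
                slopes = [lyapunov_exponent_y(tr).slope for tr in reps]
                sign[i, j] = float(np.sign(np.median(slopes)))
    return RegimeMap(axis1_name=name1, axis1_values=vals1,
                     axis2_name=name2, axis2_values=vals2,
                     r0_star=r0s, classification=cls, slope_sign=sign)


# ---------------------------------------------------------------------------
# Plain-text config I/O

def read_config(path: str | Path) -> tuple[ModelParams, SimConfig]:
    """Parse a key = value config file into (ModelParams, SimConfig).

    Model keys are exactly lambda, d (alias h), e, a, p, c, b, sigma,
    sigma1..sigma3; simulation keys (dt, t_max, seed, record_every, scheme,
    positivity_policy) are optional and fall back to SimConfig defaults.
    Unknown keys are rejected by name.
    """
    model_raw: dict[str, str] = {}
    sim_raw: dict[str, str] = {}
    unknown: list[str] = []
    model_keys = set(config_keys()) | {"h"}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', "
                             f"got {line!r}")
        key, value = (part.strip() for part in stripped.split("=", 1))
        if key in model_keys:
            model_raw[key] = value
        elif key in _SIM_KEYS:
            sim_raw[key] = value
        else:
            unknown.append(key)
    if unknown:
        raise ValueError("unknown config keys: " + ", ".join(sorted(unknown)))
    params = params_from_dict({k: float(v) for k, v in model_raw.items()})
    sim_kwargs = {k: _SIM_KEYS[k](v) for k, v in sim_raw.items()}
    return params, SimConfig(**sim_kwargs)


def write_config(params: ModelParams, path: str | Path,
                 config: SimConfig | None = None) -> None:
    """Write a config file that round-trips through :func:`read_config`."""
    lines = [f"# viralctl {__version__} parameter file"]
    for key, value in params_to_dict(params).items():
        lines.append(f"{key} = {value!r}")
    if config is not None:
        lines.append(f"dt = {config.dt!r}")
        lines.append(f"t_max = {config.t_max!r}")
        lines.append(f"seed = {config.seed}")
        lines.append(f"record_every = {config.record_every}")
        lines.append(f"scheme = {config.scheme}")
        lines.append(f"positivity_policy = {config.positivity_policy}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(traj: Trajectory, out_prefix: str | Path) -> dict[str, str]:
    """Write a trajectory CSV plus its JSON sidecar summary."""
    out_prefix = Path(out_prefix)
    csv_path = out_prefix.with_suffix(".csv")
    json_path = out_prefix.with_suffix(".json")
    traj.to_csv(csv_path, header_comment=_provenance(traj.params,
                                                     traj.config))
    traj.write_summary(json_path)
    return {"csv": str(csv_path), "summary": str(json_path)}
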
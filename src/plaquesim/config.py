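"""Configuration files, scenario presets and output writing.

Configs are TOML with three sections.  ``[parameters]`` holds nondimensional
model parameters (missing keys fall back to the standard estimates),
``[solver]`` grid/tolerance settings, and ``[scenario]`` a preset name plus
run metadata (bead tag times, run id).  Merge order is
defaults <- preset <- file <- explicit overrides; unknown keys are an error,
values outside the standard variable ranges only warn.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

try:
    import tomllib
except ModuleNotFoundError:  # python < 3.11
    import tomli as tomllib  # type: ignore

from plaquesim.model_core import PARAMETER_RANGES, ModelParameters
from plaquesim.solver import Solution, SolverConfig, conservation_report

__all__ = ["PRESETS", "load_config", "write_outputs", "format_series"]

logger = logging.getLogger("plaquesim")

#: Named scenarios: parameter/solver overrides reproducing the canonical runs.
PRESETS: Dict[str, Dict[str, Any]] = {
    "fig2_base": {
        "description": "base case, efficient efferocytosis (mu_a=40, mu_e=60, sigma_e=0)",
        "parameters": {"mu_a": 40.0, "mu_e": 60.0, "sigma_e": 0.0},
        "solver": {"t_end": 1.0},
    },
    "fig3a": {
        "description": "poor efferocytosis, no emigration (mu_e=20, sigma_e=0)",
        "parameters": {"mu_a": 40.0, "mu_e": 20.0, "sigma_e": 0.0},
        "solver": {"t_end": 1.0},
    },
    "fig3b": {
        "description": "poor efferocytosis with emigration (mu_e=20, sigma_e=30)",
        "parameters": {"mu_a": 40.0, "mu_e": 20.0, "sigma_e": 30.0},
        "solver": {"t_end": 1.0},
    },
    "fig3c": {
        "description": "efficient efferocytosis, no emigration (mu_e=80, sigma_e=0)",
        "parameters": {"mu_a": 40.0, "mu_e": 80.0, "sigma_e": 0.0},
        "solver": {"t_end": 1.0},
    },
    "fig3d": {
        "description": "efficient efferocytosis with emigration (mu_e=80, sigma_e=30)",
        "parameters": {"mu_a": 40.0, "mu_e": 80.0, "sigma_e": 30.0},
        "solver": {"t_end": 1.0},
    },
    "fig8a": {
        "description": "emigration with dead deep plaque (mu_e=20, sigma_e=40): growth unchecked",
        "parameters": {"mu_a": 40.0, "mu_e": 20.0, "sigma_e": 40.0},
        "solver": {"t_end": 3.0},
    },
    "fig8b": {
        "description": "emigration with live deep plaque (mu_e=80, sigma_e=80): stabilising",
        "parameters": {"mu_a": 40.0, "mu_e": 80.0, "sigma_e": 80.0},
        "solver": {"t_end": 3.0},
    },
    "fig10_beads": {
        "description": "bead tagging, high efferocytosis (mu_e=80, sigma_e=20, tag at t=1)",
        "parameters": {"mu_a": 40.0, "mu_e": 80.0, "sigma_e": 20.0},
        "solver": {"t_end": 4.0},
        "scenario": {"t_tags": [1.0]},
    },
    "fig13_beads": {
        "description": "bead tagging, poor efferocytosis (mu_e=30, sigma_e=40, tag at t=0.5)",
        "parameters": {"mu_a": 40.0, "mu_e": 30.0, "sigma_e": 40.0},
        "solver": {"t_end": 3.0},
        "scenario": {"t_tags": [0.5]},
    },
}

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_SOLVER_KEYS = {f.name for f in dataclasses.fields(SolverConfig)}
_SCENARIO_KEYS = {"preset", "t_tags", "run_id"}


def _check_ranges(params: Mapping[str, float]) -> None:
    for name, (lo, hi) in PARAMETER_RANGES.items():
        if name in params and not (lo <= params[name] <= hi):
            logger.warning(
                "parameter %s=%g outside the standard range [%g, %g]",
                name, params[name], lo, hi,
            )


def load_config(
    path: Optional[str | Path] = None,
    preset: Optional[str] = None,
    overrides: Optional[Mapping[str, Mapping[str, Any]]] = None,
) -> Tuple[ModelParameters, SolverConfig, Dict[str, Any]]:
    """Build (ModelParameters, SolverConfig, scenario) from defaults, an
    optional preset, an optional TOML file and explicit overrides, merged in
    that order (later wins).  Unknown keys raise ValueError listing the valid
    ones; values outside the standard variable ranges warn but are accepted.
    """
    param_kv: Dict[str, Any] = {}
    solver_kv: Dict[str, Any] = {}
    scenario: Dict[str, Any] = {"preset": None, "t_tags": [], "run_id": "run"}

    file_kv: Dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            file_kv = tomllib.load(fh)
        unknown_sections = set(file_kv) - {"parameters", "solver", "scenario"}
        if unknown_sections:
            raise ValueError(
                f"unknown config sections {sorted(unknown_sections)}; "
                "valid: parameters, solver, scenario"
            )
        if preset is None:
            preset = file_kv.get("scenario", {}).get("preset")

    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; valid: {sorted(PRESETS)}")
        spec = PRESETS[preset]
        param_kv.update(spec.get("parameters", {}))
        solver_kv.update(spec.get("solver", {}))
        scenario.update(spec.get("scenario", {}))
        scenario["preset"] = preset

    for section, sink, valid in (
        ("parameters", param_kv, _PARAM_KEYS),
        ("solver", solver_kv, _SOLVER_KEYS),
        ("scenario", scenario, _SCENARIO_KEYS),
    ):
        data = dict(file_kv.get(section, {}))
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown keys {sorted(unknown)} in [{section}]; valid: {sorted(valid)}"
            )
        sink.update(data)

    if overrides:
        param_kv.update(overrides.get("parameters", {}))
        solver_kv.update(overrides.get("solver", {}))
        scenario.update(overrides.get("scenario", {}))

    _check_ranges(param_kv)
    if "output_times" in solver_kv and solver_kv["output_times"] is not None:
        solver_kv["output_times"] = tuple(solver_kv["output_times"])
    params = ModelParameters(**param_kv)
    cfg = SolverConfig(**solver_kv)
    logger.info("config: preset=%s params=%s solver=%s",
                scenario.get("preset"), params, cfg)
    return params, cfg, scenario


def format_series(df: pd.DataFrame) -> str:
    """Render a scalar table as TSV with 12-significant-digit scientific
    floats (byte-stable across reruns of a deterministic model)."""
    return df.to_csv(sep="\t", index=False, float_format="%.12e")


def _config_echo(params: ModelParameters, cfg: SolverConfig,
                 scenario: Mapping[str, Any]) -> str:
    payload = {
        "parameters": dataclasses.asdict(params),
        "solver": dataclasses.asdict(cfg),
        "scenario": dict(scenario),
    }
    return json.dumps(payload, indent=2, sort_keys=True, default=list) + "\n"


def write_outputs(
    sol: Solution,
    destination: str | Path,
    run_id: str = "run",
    scenario: Optional[Mapping[str, Any]] = None,
) -> Dict[str, Path]:
    """Write the standard file set for a run; returns the file manifest.

    ``{run_id}_series.tsv`` holds the scalar time series (R, dR/dt, totals,
    boundary fluxes, residuals), ``{run_id}_profiles.nc`` the spatial
    snapshots as a self-describing netCDF array container (y, x, f, l, c, v
    and bead densities when present), and ``{run_id}_config_echo.json`` the
    fully-merged configuration.
    """
    import xarray as xr

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Path] = {}

    series = sol.diagnostics.copy()
    report = conservation_report(sol)
    series["mass_vs_R"] = report["mass_vs_R"].to_numpy()
    series["mass_budget_residual"] = report["mass_budget_residual"].to_numpy()
    series_path = dest / f"{run_id}_series.tsv"
    series_path.write_text(format_series(series))
    manifest["series"] = series_path

    v = np.stack([sol.velocity_profile(i) for i in range(sol.n_times)])
    data = {
        "f": (("t", "y"), sol.f),
        "l": (("t", "y"), sol.l),
        "c": (("t", "y"), sol.c),
        "v": (("t", "y"), v),
        "x": (("t", "y"), np.outer(sol.R, sol.y_grid)),
        "R": (("t",), sol.R),
    }
    if hasattr(sol, "q_f") and getattr(sol, "q_f") is not None:
        data["q_f"] = (("t", "y"), sol.q_f)
        data["q_c"] = (("t", "y"), sol.q_c)
    ds = xr.Dataset(data, coords={"t": sol.t, "y": sol.y_grid})
    ds.attrs["description"] = "plaquesim profile snapshots on the mapped unit grid"
    profiles_path = dest / f"{run_id}_profiles.nc"
    ds.to_netcdf(profiles_path, engine="scipy")
    manifest["profiles"] = profiles_path

    echo_path = dest / f"{run_id}_config_echo.json"
    echo_path.write_text(_config_echo(sol.params, sol.config, scenario or {}))
    manifest["config_echo"] = echo_path

    if hasattr(sol, "q_f") and getattr(sol, "q_f") is not None:
        from plaquesim.beads import circulation_time, total_beads

        Q = total_beads(sol)
        q_path = dest / f"{run_id}_beads.tsv"
        q_path.write_text(format_series(pd.DataFrame({"t": Q.index, "Q": Q.values})))
        manifest["beads"] = q_path
        tc = circulation_time(Q)
        summary = pd.DataFrame([{
            "t_tags": ",".join(f"{x:g}" for x in sol.t_tags),
            "t_circ": tc.value,
            "censored": tc.censored,
        }])
        tc_path = dest / f"{run_id}_tcirc.tsv"
        tc_path.write_text(format_series(summary))
        manifest["tcirc"] = tc_path

    logger.info("wrote %d files to %s", len(manifest), dest)
    return manifest
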
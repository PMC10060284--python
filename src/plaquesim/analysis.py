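"""Scalar summaries and parameter-sweep drivers.

Post-processing of runs into the quantities used to characterise plaque
fate: total phase contents, the deep-plaque (medial) foam-cell density, the
intima growth rate and the emigration flux, plus a cross-product sweep
driver that tabulates these over grids of the variable parameters
(mu_a, mu_e, sigma_e, ...).
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from plaquesim.model_core import ModelParameters, endothelial_value, medial_value
from plaquesim.solver import SolverConfig, Solution, simulate

__all__ = [
    "phase_totals",
    "medial_density",
    "growth_rate",
    "emigration_flux",
    "run_sweep",
]

logger = logging.getLogger("plaquesim")

#: Hard cap on the number of simulations a single sweep may launch.
MAX_SWEEP_RUNS = 512


def phase_totals(sol: Solution) -> pd.DataFrame:
    """Total phase contents int_0^R u dx for u in {f, l, c} per snapshot.

    Midpoint quadrature on the cell-averaged fields (exact for the
    finite-volume representation); the three totals sum to R(t) up to the
    voids tolerance.
    """
    h = 1.0 / sol.config.n_cells
    return pd.DataFrame({
        "t": sol.t,
        "int_f": h * sol.R * sol.f.sum(axis=1),
        "int_l": h * sol.R * sol.l.sum(axis=1),
        "int_c": h * sol.R * sol.c.sum(axis=1),
    })


def _interp_series(t_snap: np.ndarray, values: np.ndarray, t: float) -> float:
    if t < t_snap[0] - 1e-12 or t > t_snap[-1] + 1e-12:
        raise ValueError(f"t={t} outside solution range [{t_snap[0]}, {t_snap[-1]}]")
    return float(np.interp(t, t_snap, values))


def medial_density(sol: Solution, t: float) -> float:
    """Foam-cell fraction at the medial boundary f|x=R, linearly interpolated in t."""
    fR = np.array([medial_value(sol.f[i]) for i in range(sol.n_times)])
    return _interp_series(sol.t, fR, t)


def growth_rate(sol: Solution, t: float) -> float:
    """Intima growth rate dR/dt evaluated from the boundary fluxes at time t."""
    return _interp_series(sol.t, sol.diagnostics["dR_dt"].to_numpy(), t)


def emigration_flux(sol: Solution, t: float) -> float:
    """Foam-cell emigration flux sigma_e * f|x=R at time t."""
    return _interp_series(sol.t, sol.diagnostics["flux_egress"].to_numpy(), t)


def run_sweep(
    base: ModelParameters,
    sweep: Mapping[str, Sequence[float]],
    cfg: SolverConfig,
    t_eval: float | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Run one simulation per parameter combination and tabulate summaries.

    ``sweep`` maps ModelParameters field names to value lists; the cross
    product is enumerated in deterministic (insertion, row-major) order.  An
    empty mapping yields the single base-case row.  ``t_eval`` lists the
    evaluation times for the scalar summaries (default: t_end).  Failures of
    individual runs are recorded in the ``error`` column and the sweep
    continues.

    Returns one row per (combination, t_eval) with columns for the swept
    values, R, dR/dt, f|R, the emigration flux and the phase totals.
    """
    names = list(sweep.keys())
    for name in names:
        if not hasattr(base, name):
            raise ValueError(f"unknown parameter {name!r} in sweep spec")
        if len(sweep[name]) == 0:
            raise ValueError(f"empty value list for sweep parameter {name!r}")
    combos = list(itertools.product(*(sweep[n] for n in names))) or [()]
    if len(combos) > MAX_SWEEP_RUNS:
        raise ValueError(f"sweep would launch {len(combos)} runs (cap {MAX_SWEEP_RUNS})")
    if t_eval is None:
        t_eval = [cfg.t_end]
    elif np.isscalar(t_eval):
        t_eval = [float(t_eval)]
    else:
        t_eval = [float(x) for x in t_eval]

    rows = []
    for combo in combos:
        overrides = dict(zip(names, combo))
        try:
            params = base.replace(**overrides)
            sol = simulate(params, cfg)
            totals = phase_totals(sol)
            for te in t_eval:
                rows.append({
                    **overrides,
                    "t_eval": te,
                    "R": sol.interp_R(te),
                    "dR_dt": growth_rate(sol, te),
                    "f_media": medial_density(sol, te),
                    "emigration_flux": emigration_flux(sol, te),
                    "int_f": _interp_series(sol.t, totals["int_f"].to_numpy(), te),
                    "int_l": _interp_series(sol.t, totals["int_l"].to_numpy(), te),
                    "int_c": _interp_series(sol.t, totals["int_c"].to_numpy(), te),
                    "error": "",
                })
        except Exception as exc:  # record and continue per sweep contract
            logger.warning("sweep run %s failed: %s", overrides, exc)
            for te in t_eval:
                rows.append({**overrides, "t_eval": te, "R": np.nan,
                             "dR_dt": np.nan, "f_media": np.nan,
                             "emigration_flux": np.nan, "int_f": np.nan,
                             "int_l": np.nan, "int_c": np.nan,
                             "error": f"{type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)
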
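"""Shared simulation fixtures.

Full-resolution runs (n_cells=200) are used where a quantitative value is
asserted; trend and sweep fixtures use n_cells=100, which the grid-convergence
study shows changes the scalar summaries by well under 1%.
"""

from __future__ import annotations

import numpy as np
import pytest

from plaquesim import (
    ModelParameters,
    SolverConfig,
    PRESETS,
    run_sweep,
    simulate,
    simulate_with_beads,
)


@pytest.fixture(scope="session")
def base80_n200():
    """Efficient-efferocytosis scenario (mu_e=80, sigma_e=0) at full resolution."""
    return simulate(ModelParameters(mu_e=80.0), SolverConfig(n_cells=200, t_end=1.0))


@pytest.fixture(scope="session")
def base80_n400(base80_n200):
    return simulate(base80_n200.params, SolverConfig(n_cells=400, t_end=1.0))


@pytest.fixture(scope="session")
def base80_n100(base80_n200):
    return simulate(base80_n200.params, SolverConfig(n_cells=100, t_end=1.0))


@pytest.fixture(scope="session")
def preset_runs():
    """One solution per scenario preset (bead presets co-integrate tracers)."""
    out = {}
    for name, spec in PRESETS.items():
        params = ModelParameters(**spec.get("parameters", {}))
        cfg = SolverConfig(n_cells=200, **spec.get("solver", {}))
        t_tags = spec.get("scenario", {}).get("t_tags")
        if t_tags:
            out[name] = simulate_with_beads(params, cfg, t_tags)
        else:
            out[name] = simulate(params, cfg)
    return out


@pytest.fixture(scope="session")
def emigration_sweep():
    """dR/dt, f|R and emigration flux at t=1 over (mu_e, sigma_e) grids."""
    return run_sweep(
        ModelParameters(mu_a=40.0),
        {"mu_e": [20.0, 80.0], "sigma_e": [0.0, 20.0, 40.0, 80.0, 100.0]},
        SolverConfig(n_cells=100, t_end=1.0),
        t_eval=1.0,
    )


@pytest.fixture(scope="session")
def mu_e_sweep():
    """Growth rate and medial density at t=1 across efferocytosis rates."""
    return run_sweep(
        ModelParameters(mu_a=40.0, sigma_e=0.0),
        {"mu_e": [20.0, 40.0, 60.0, 80.0, 120.0]},
        SolverConfig(n_cells=100, t_end=1.0),
        t_eval=1.0,
    )


@pytest.fixture(scope="session")
def long_emigration_runs():
    """mu_e=80 runs to t=3 over sigma_e, for the plaque-stabilisation trends."""
    out = {}
    for sigma_e in (0.0, 20.0, 40.0, 80.0):
        out[sigma_e] = simulate(
            ModelParameters(mu_e=80.0, sigma_e=sigma_e),
            SolverConfig(n_cells=100, t_end=3.0),
        )
    return out


@pytest.fixture(scope="session")
def bead_conserved_run():
    """Single dose with sigma_e=0: beads have no exit path."""
    return simulate_with_beads(
        ModelParameters(mu_e=60.0), SolverConfig(n_cells=100, t_end=1.0),
        t_tags=[0.3],
    )


@pytest.fixture(scope="session")
def tcirc_runs():
    """Bead runs for the circulation-time trends in sigma_e and t_tag."""
    out = {}
    for sigma_e, t_tag, t_end in [
        (20.0, 0.5, 4.0),
        (20.0, 1.0, 4.0),
        (20.0, 1.5, 5.0),
        (40.0, 1.0, 4.0),
    ]:
        out[(sigma_e, t_tag)] = simulate_with_beads(
            ModelParameters(mu_e=80.0, sigma_e=sigma_e),
            SolverConfig(n_cells=100, t_end=t_end),
            t_tags=[t_tag],
        )
    return out
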
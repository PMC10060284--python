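"""Deep-plaque dynamics along advection characteristics.

Away from the endothelium the interphase (diffusive and chemotactic) fluxes
are dominated by bulk advection and the modLDL fraction is negligible, so the
foam-cell fraction F observed along a material characteristic obeys the
scalar logistic-type ODE

    dF/dt = mu_e * F * ((1 - mu_a/mu_e) - F) ,

with the dead-material fraction C = 1 - F.  The ODE has steady states at
F* = 0 and F* = 1 - mu_a/mu_e that exchange stability in a transcritical
bifurcation at mu_a = mu_e: efferocytosis strong enough to outpace cell death
(mu_e > mu_a) sustains a live foam-cell population in the deep plaque, while
weaker efferocytosis drives it extinct.  The linearised eigenvalues are
mu_e - mu_a at F* = 0 and mu_a - mu_e at the coexistence state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SteadyState",
    "characteristic_rhs",
    "steady_states",
    "stability_eigenvalues",
    "solve_characteristic",
    "logistic_solution",
    "bifurcation_table",
]


@dataclass(frozen=True)
class SteadyState:
    """A steady state of the characteristic ODE with its stability label."""

    F: float
    stability: str  # "stable" | "unstable" | "degenerate"
    eigenvalue: float


def characteristic_rhs(F: float | np.ndarray, mu_a: float, mu_e: float):
    """dF/dt = mu_e F ((1 - mu_a/mu_e) - F); pure decay -mu_a F when mu_e = 0."""
    F = np.asarray(F, dtype=float)
    if mu_e == 0.0:
        out = -mu_a * F
    else:
        out = mu_e * F * ((1.0 - mu_a / mu_e) - F)
    return float(out) if out.ndim == 0 else out


def stability_eigenvalues(mu_a: float, mu_e: float) -> Dict[float, float]:
    """Linearised growth rates at each steady state of the characteristic ODE.

    Returns a map F* -> lambda with lambda = mu_e - mu_a at F* = 0 and
    lambda = mu_a - mu_e at the coexistence state F* = 1 - mu_a/mu_e
    (reported only when that state is strictly positive).
    """
    _validate_rates(mu_a, mu_e)
    eigs = {0.0: mu_e - mu_a}
    if mu_e > 0 and 1.0 - mu_a / mu_e > 0:
        eigs[1.0 - mu_a / mu_e] = mu_a - mu_e
    return eigs


def steady_states(mu_a: float, mu_e: float) -> List[SteadyState]:
    """Nonnegative steady states of the characteristic ODE with stability.

    Below the transcritical point (mu_e < mu_a) only extinction F* = 0 exists
    and it is stable; above it (mu_e > mu_a) extinction destabilises and the
    coexistence state F* = 1 - mu_a/mu_e appears, stable.  At mu_a = mu_e the
    two collide in a single degenerate state with zero eigenvalue.
    """
    _validate_rates(mu_a, mu_e)
    out: List[SteadyState] = []
    for F_star, lam in sorted(stability_eigenvalues(mu_a, mu_e).items()):
        if lam < 0:
            label = "stable"
        elif lam > 0:
            label = "unstable"
        else:
            label = "degenerate"
        out.append(SteadyState(F=F_star, stability=label, eigenvalue=lam))
    return out


def logistic_solution(F0: float, mu_a: float, mu_e: float,
                      t: float | np.ndarray) -> np.ndarray:
    """Closed-form solution of the characteristic ODE from F(0) = F0.

    For K = 1 - mu_a/mu_e != 0 this is the logistic curve
    F(t) = K / (1 + ((K - F0)/F0) exp(-(mu_e - mu_a) t)) (exponential decay
    toward 0 when K < 0 follows from the same formula); degenerate cases
    (F0 = 0, mu_e = 0, mu_a = mu_e) are handled by their exact limits.
    """
    _validate_rates(mu_a, mu_e)
    t = np.asarray(t, dtype=float)
    if F0 == 0.0:
        return np.zeros_like(t)
    if mu_e == 0.0:
        return F0 * np.exp(-mu_a * t)
    K = 1.0 - mu_a / mu_e
    if K == 0.0:
        # dF/dt = -mu_e F^2  ->  algebraic decay
        return F0 / (1.0 + mu_e * F0 * t)
    r = mu_e - mu_a
    return K / (1.0 + ((K - F0) / F0) * np.exp(-r * t))


def solve_characteristic(F0: float, mu_a: float, mu_e: float,
                         t_grid: Sequence[float]) -> np.ndarray:
    """Numerically integrate the characteristic ODE on the given time grid."""
    if not (0.0 <= F0 <= 1.0):
        raise ValueError(f"F0 must lie in [0, 1], got {F0}")
    _validate_rates(mu_a, mu_e)
    t_grid = np.asarray(t_grid, dtype=float)
    res = solve_ivp(
        lambda t, F: characteristic_rhs(F, mu_a, mu_e),
        (t_grid[0], t_grid[-1]), [F0], t_eval=t_grid,
        method="LSODA", rtol=1e-10, atol=1e-13,
    )
    if not res.success:
        raise RuntimeError(f"characteristic ODE integration failed: {res.message}")
    return res.y[0]


def bifurcation_table(ratios: Sequence[float], mu_a: float = 40.0) -> pd.DataFrame:
    """Steady states and eigenvalues over a grid of efferocytosis/death ratios.

    One row per (mu_e/mu_a, F*) pair; used to trace the transcritical
    exchange of stability across the ratio-1 point.
    """
    rows = []
    for ratio in ratios:
        mu_e = ratio * mu_a
        for ss in steady_states(mu_a, mu_e):
            rows.append({
                "mu_e_over_mu_a": ratio,
                "mu_a": mu_a,
                "mu_e": mu_e,
                "F_star": ss.F,
                "eigenvalue": ss.eigenvalue,
                "stability": ss.stability,
            })
    return pd.DataFrame(rows)


def _validate_rates(mu_a: float, mu_e: float) -> None:
    if mu_a < 0 or mu_e < 0:
        raise ValueError("mu_a and mu_e must be nonnegative")
    if mu_a == 0 and mu_e == 0:
        raise ValueError("mu_a and mu_e cannot both be zero")
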
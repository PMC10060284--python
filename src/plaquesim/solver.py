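"""Method-of-lines integration of the free-boundary multiphase system.

The moving domain [0, R(t)] is mapped to the fixed unit interval via
y = x / R(t), which turns the free-boundary problem into a fixed-domain
system of parabolic PDEs coupled to an ODE for R.  In conservative form the
mapped equations read

    du/dt = (1/R) d/dy [ y R' u - j_u ] - (R'/R) u + s_u ,

with j_u = J_u + v u the total phase flux in physical coordinates.  Space is
discretised with a cell-centred finite-volume scheme on a uniform y-grid:
face gradients are exact central differences, face values are arithmetic
means (second order; an upwind option exists for high-Peclet robustness),
and the flux boundary conditions enter directly as the prescribed fluxes on
the two boundary faces.  This construction conserves total mass exactly and
preserves the no-voids sum f + l + c = 1 as an invariant of the
semi-discrete system, so the voids residual of a run sits at the
ODE-integrator tolerance rather than at the truncation-error level.  The
resulting stiff ODE system is advanced with SciPy's BDF integrator using an
explicit Jacobian sparsity pattern (block-tridiagonal plus the dense
couplings through the boundary values l|0, f|R and R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from plaquesim.model_core import (
    ModelParameters,
    PlaqueState,
    endothelial_value,
    medial_value,
    source_terms,
)

__all__ = [
    "SolverConfig",
    "Solution",
    "simulate",
    "conservation_report",
    "IntegrationError",
    "ModelConsistencyError",
]

logger = logging.getLogger("plaquesim")

#: Regularisation threshold for tracer/carrier flux ratios (beads module).
EPS_RATIO = 1e-10


class IntegrationError(RuntimeError):
    """Time integration failed; carries the last valid packed state."""

    def __init__(self, message: str, last_state: Optional[np.ndarray] = None,
                 last_time: Optional[float] = None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


class ModelConsistencyError(RuntimeError):
    """A physical invariant (no-voids, positivity) was breached far beyond tolerance."""


@dataclass(frozen=True)
class SolverConfig:
    """Grid, tolerance and output settings for :func:`simulate`.

    ``n_cells`` is the number of finite-volume cells on the unit y-grid;
    ``rtol``/``atol`` are passed to the BDF integrator.  ``tol_voids`` and
    ``tol_neg`` are monitoring tolerances: stored states beyond them trigger
    a warning, beyond ten times them a hard :class:`ModelConsistencyError`.
    ``seed`` is reserved (the model is deterministic and consumes no
    randomness).
    """

    n_cells: int = 200
    t_end: float = 1.0
    output_times: Optional[Tuple[float, ...]] = None
    rtol: float = 1e-8
    atol: float = 1e-10
    advection_scheme: str = "central"
    tol_voids: float = 1e-4
    tol_neg: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 16:
            raise ValueError("n_cells must be >= 16")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("rtol and atol must be positive")
        if self.advection_scheme not in ("central", "upwind"):
            raise ValueError("advection_scheme must be 'central' or 'upwind'")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.output_times is not None:
            ts = np.asarray(self.output_times, dtype=float)
            if ts.size < 2 or np.any(np.diff(ts) <= 0):
                raise ValueError("output_times must be strictly increasing with >= 2 entries")
            if ts[0] < 0 or ts[-1] > self.t_end + 1e-12:
                raise ValueError("output_times must lie within [0, t_end]")

    def replace(self, **kwargs) -> "SolverConfig":
        return replace(self, **kwargs)

    def resolved_output_times(self) -> np.ndarray:
        """Snapshot times: the configured ones, or a default grid with spacing
        <= 0.01 (dense enough to resolve bead dose windows and t-interpolation)."""
        if self.output_times is not None:
            ts = np.asarray(self.output_times, dtype=float)
            if ts[0] > 0:
                ts = np.concatenate([[0.0], ts])
            return ts
        n = max(101, int(round(self.t_end / 0.01)) + 1)
        base = np.linspace(0.0, self.t_end, n)
        # extra resolution across the initial influx ramp so that
        # finite-difference diagnostics of R(t) resolve the transient
        early = np.arange(0.0, min(0.06, self.t_end), 2.5e-4)
        return np.unique(np.concatenate([base, early]))


class _Discretisation:
    """Finite-volume right-hand side for the packed state [fields..., R].

    ``n_fields`` is 3 for the phase-only model and 5 with the bead tracers
    (q_f, q_c appended).  ``dose`` is the endothelial bead influx as a
    function of time (zero for the phase-only model).
    """

    def __init__(self, p: ModelParameters, cfg: SolverConfig, n_fields: int = 3,
                 dose: Optional[Callable[[float], float]] = None):
        self.p = p
        self.cfg = cfg
        self.nf = n_fields
        self.N = cfg.n_cells
        self.h = 1.0 / self.N
        self.y_centers = (np.arange(self.N) + 0.5) * self.h
        self.y_faces_int = np.arange(1, self.N) * self.h
        self.dose = dose if dose is not None else (lambda t: 0.0)
        self.upwind = cfg.advection_scheme == "upwind"
        # scratch flux array (nf, N+1 faces)
        self._G = np.empty((self.nf, self.N + 1))

    # -- state packing ---------------------------------------------------
    def pack(self, fields: np.ndarray, R: float) -> np.ndarray:
        return np.concatenate([np.asarray(fields, dtype=float).ravel(), [R]])

    def unpack(self, Y: np.ndarray) -> Tuple[np.ndarray, float]:
        return Y[:-1].reshape(self.nf, self.N), float(Y[-1])

    def initial_state(self) -> np.ndarray:
        """Uniform resident-macrophage intima: f=1, l=c=0 (and no beads), R=1."""
        fields = np.zeros((self.nf, self.N))
        fields[0] = 1.0
        return self.pack(fields, 1.0)

    # -- right-hand side -------------------------------------------------
    def rhs(self, t: float, Y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(Y)):
            bad = int(np.flatnonzero(~np.isfinite(Y))[0])
            raise IntegrationError(
                f"non-finite state entry at packed index {bad} (t={t:.6g})",
                last_state=Y, last_time=t,
            )
        p = self.p
        u, R = self.unpack(Y)
        f, l, c = u[0], u[1], u[2]

        l0 = endothelial_value(l)
        fR = medial_value(f)
        v_in = p.sigma_f * l0 + p.sigma_l
        Rp = v_in - p.sigma_e * fR

        # face gradients (w.r.t. physical x) and arithmetic-mean face values
        inv_hR = 1.0 / (self.h * R)
        grad = (u[:, 1:] - u[:, :-1]) * inv_hR
        um = 0.5 * (u[:, 1:] + u[:, :-1])
        fbar = um[0]

        J = np.empty((self.nf, self.N - 1))
        J[0] = -p.D_f * grad[0] + p.chi_l * fbar * grad[1] + p.chi_c * fbar * grad[2]
        J[1] = -p.D_l * grad[1]
        J[2] = -p.D_c * grad[2]
        v_face = v_in - (J[0] + J[1] + J[2])
        if self.nf == 5:
            # tracers ride their carrier phase: J_q = (q/u_carrier) J_carrier
            cbar = um[2]
            J[3] = np.where(fbar > EPS_RATIO, um[3] / np.where(fbar > EPS_RATIO, fbar, 1.0), 0.0) * J[0]
            J[4] = np.where(cbar > EPS_RATIO, um[4] / np.where(cbar > EPS_RATIO, cbar, 1.0), 0.0) * J[2]

        w = v_face - self.y_faces_int * Rp  # advection speed relative to the grid
        if self.upwind:
            uface = np.where(w > 0, u[:, :-1], u[:, 1:])
        else:
            uface = um
        G = self._G
        # G = y R' u - j_u = -(J_u + w u) at a face
        G[:, 1:-1] = -(J + w * uface)

        # boundary faces carry the prescribed fluxes directly
        G[:, 0] = 0.0
        G[:, -1] = 0.0
        G[0, 0] = -p.sigma_f * l0          # monocyte recruitment
        G[1, 0] = -p.sigma_l               # LDL deposition
        G[0, -1] = -p.sigma_e * fR         # foam-cell emigration
        if self.nf == 5:
            G[3, 0] = -self.dose(t)        # bead-tagged monocyte influx
            G[3, -1] = -p.sigma_e * medial_value(u[3])

        dudt = (G[:, 1:] - G[:, :-1]) * inv_hR - (Rp / R) * u
        s_f, s_l, s_c = source_terms(f, l, c, p)
        dudt[0] += s_f
        dudt[1] += s_l
        dudt[2] += s_c
        if self.nf == 5:
            transfer = p.mu_a * u[3] - p.mu_e * f * u[4]
            dudt[3] -= transfer
            dudt[4] += transfer

        out = np.empty_like(Y)
        out[:-1] = dudt.ravel()
        out[-1] = Rp
        return out

    # -- Jacobian sparsity -----------------------------------------------
    def jac_sparsity(self) -> lil_matrix:
        nf, N = self.nf, self.N
        n = nf * N + 1
        S = lil_matrix((n, n), dtype=np.int8)
        ones3 = np.ones(3, dtype=np.int8)
        for i in range(N):
            lo, hi = max(0, i - 1), min(N - 1, i + 1)
            width = hi - lo + 1
            for k in range(nf):
                row = k * N + i
                for m in range(nf):
                    S[row, m * N + lo:m * N + hi + 1] = ones3[:width]
        # global couplings: v_in via l|0 (cells 0,1 of l), R' via f|R
        # (cells N-2, N-1 of f and, with beads, of q_f), and R itself
        dense_cols = [N + 0, N + 1, N - 2, N - 1, n - 1]
        if nf == 5:
            dense_cols += [3 * N + N - 2, 3 * N + N - 1]
        for col in dense_cols:
            S[:, col] = 1
        S[n - 1, :] = 0
        for col in dense_cols:
            S[n - 1, col] = 1
        return S


@dataclass
class Solution:
    """Time-ordered snapshots of a run plus per-snapshot diagnostics.

    Field arrays have shape (n_times, n_cells) on the fixed y-grid; physical
    positions are reconstructed as x = y * R(t).  ``diagnostics`` holds one
    row per snapshot: R, dR/dt, boundary values and fluxes, the no-voids
    residual and the most negative phase value.
    """

    t: np.ndarray
    y_grid: np.ndarray
    f: np.ndarray
    l: np.ndarray
    c: np.ndarray
    R: np.ndarray
    params: ModelParameters
    config: SolverConfig
    diagnostics: pd.DataFrame
    stats: dict

    @property
    def n_times(self) -> int:
        return len(self.t)

    def state(self, i: int) -> PlaqueState:
        return PlaqueState(
            y_grid=self.y_grid, f=self.f[i], l=self.l[i], c=self.c[i],
            R=float(self.R[i]), t=float(self.t[i]),
        )

    @property
    def states(self):
        return [self.state(i) for i in range(self.n_times)]

    @property
    def R_series(self) -> pd.Series:
        return pd.Series(self.R, index=self.t, name="R")

    def velocity_profile(self, i: int) -> np.ndarray:
        """Mixture velocity at cell centres of snapshot i (centred gradients)."""
        p = self.params
        R = self.R[i]
        x = self.y_grid * R
        gf = np.gradient(self.f[i], x)
        gl = np.gradient(self.l[i], x)
        gc = np.gradient(self.c[i], x)
        l0 = endothelial_value(self.l[i])
        J_sum = (
            -p.D_f * gf + p.chi_l * self.f[i] * gl + p.chi_c * self.f[i] * gc
            - p.D_l * gl - p.D_c * gc
        )
        return p.sigma_f * l0 + p.sigma_l - J_sum

    def interp_R(self, t: float) -> float:
        return float(np.interp(t, self.t, self.R))


def _diagnostics_frame(disc: _Discretisation, t: np.ndarray, fields: np.ndarray,
                       R: np.ndarray) -> pd.DataFrame:
    p = disc.p
    h = disc.h
    rows = []
    for i, ti in enumerate(t):
        f, l, c = fields[0, :, i], fields[1, :, i], fields[2, :, i]
        l0 = endothelial_value(l)
        fR = medial_value(f)
        total = f + l + c
        rows.append({
            "t": ti,
            "R": R[i],
            "dR_dt": p.sigma_f * l0 + p.sigma_l - p.sigma_e * fR,
            "l_endo": l0,
            "f_media": fR,
            "flux_monocyte": p.sigma_f * l0,
            "flux_ldl": p.sigma_l,
            "flux_egress": p.sigma_e * fR,
            "int_f": h * R[i] * f.sum(),
            "int_l": h * R[i] * l.sum(),
            "int_c": h * R[i] * c.sum(),
            "voids_max": float(np.max(np.abs(total - 1.0))),
            "min_phase": float(min(f.min(), l.min(), c.min())),
        })
    return pd.DataFrame(rows)


def _monitor_invariants(diag: pd.DataFrame, cfg: SolverConfig) -> None:
    worst_voids = diag["voids_max"].max()
    worst_neg = diag["min_phase"].min()
    if worst_voids > 10 * cfg.tol_voids or worst_neg < -10 * cfg.tol_neg:
        raise ModelConsistencyError(
            f"invariant breach: max voids residual {worst_voids:.3e} "
            f"(tol {cfg.tol_voids:.1e}), min phase {worst_neg:.3e} "
            f"(tol -{cfg.tol_neg:.1e})"
        )
    if worst_voids > cfg.tol_voids:
        logger.warning("voids residual %.3e exceeds tol_voids %.1e",
                       worst_voids, cfg.tol_voids)
    if worst_neg < -cfg.tol_neg:
        logger.warning("phase undershoot %.3e exceeds tol_neg %.1e",
                       worst_neg, cfg.tol_neg)


def _integrate(disc: _Discretisation, y0: Optional[np.ndarray] = None):
    cfg = disc.cfg
    if y0 is None:
        y0 = disc.initial_state()
    t_eval = cfg.resolved_output_times()
    res = solve_ivp(
        disc.rhs, (t_eval[0], cfg.t_end), y0, method="BDF",
        t_eval=t_eval, rtol=cfg.rtol, atol=cfg.atol,
        jac_sparsity=disc.jac_sparsity(),
    )
    if not res.success:
        last = res.y[:, -1] if res.y.size else y0
        last_t = res.t[-1] if res.t.size else t_eval[0]
        raise IntegrationError(
            f"BDF integration failed: {res.message}", last_state=last, last_time=last_t
        )
    fields = res.y[:-1].reshape(disc.nf, disc.N, len(res.t))
    R = res.y[-1]
    stats = {"nfev": int(res.nfev), "njev": int(res.njev), "nlu": int(res.nlu),
             "n_steps": len(res.t)}
    return res.t, fields, R, stats


def simulate(p: ModelParameters, cfg: SolverConfig,
             initial_state: Optional[PlaqueState] = None) -> Solution:
    """Integrate the three-phase free-boundary system over [0, t_end].

    Starts from the homogeneous resident-macrophage state (f=1, l=c=0, R=1)
    unless ``initial_state`` provides cell-centred fields on the configured
    grid.  Raises :class:`IntegrationError` on integrator failure and
    :class:`ModelConsistencyError` if a stored snapshot breaches the no-voids
    or positivity invariants at ten times the configured tolerance.
    """
    logger.info("simulate: %s", p)
    disc = _Discretisation(p, cfg, n_fields=3)
    y0 = None
    if initial_state is not None:
        if len(initial_state.f) != cfg.n_cells:
            raise ValueError("initial_state grid does not match n_cells")
        y0 = disc.pack(np.stack([initial_state.f, initial_state.l, initial_state.c]),
                       initial_state.R)
    t, fields, R, stats = _integrate(disc, y0)
    diag = _diagnostics_frame(disc, t, fields, R)
    _monitor_invariants(diag, cfg)
    logger.info("simulate done: %d snapshots, R(end)=%.4f, stats=%s",
                len(t), R[-1], stats)
    return Solution(
        t=t, y_grid=disc.y_centers,
        f=fields[0].T.copy(), l=fields[1].T.copy(), c=fields[2].T.copy(),
        R=R.copy(), params=p, config=cfg, diagnostics=diag, stats=stats,
    )


def conservation_report(sol: Solution) -> pd.DataFrame:
    """Per-snapshot conservation diagnostics.

    Columns: the max-norm no-voids residual; the residual of the integrated
    constraint |int (f+l+c) dx - R|; and the global mass-budget residual
    |d/dt int (f+l+c) dx - (sigma_f l|0 + sigma_l - sigma_e f|R)| with the
    time derivative estimated by central finite differences of the stored
    totals (one-sided at the ends).
    """
    if sol.n_times < 2:
        raise ValueError("conservation report needs at least 2 snapshots")
    diag = sol.diagnostics
    total = (diag["int_f"] + diag["int_l"] + diag["int_c"]).to_numpy()
    t = sol.t
    d_total = np.gradient(total, t, edge_order=2)
    budget = diag["dR_dt"].to_numpy()
    return pd.DataFrame({
        "t": t,
        "voids_max": diag["voids_max"].to_numpy(),
        "total_mass": total,
        "mass_vs_R": np.abs(total - sol.R),
        "mass_budget_residual": np.abs(d_total - budget),
    })
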
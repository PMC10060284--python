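"""Parameters, state containers and pointwise physics of the nondimensional model.

The nondimensional model is posed on the moving interval ``[0, R(t)]`` with
phase volume fractions ``f`` (foam cells), ``l`` (modLDL) and ``c`` (dead
material) that sum to one (no-voids condition).  This module holds the
parameter containers, the nondimensionalisation map, and the pointwise
physics: mass-exchange source terms, interphase (non-advective) fluxes, the
closed-form mixture velocity and the free-boundary growth law.  All gradients
passed to these functions are with respect to the *physical* coordinate x; on
the mapped unit grid used by the solver this means (1/R) d/dy.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "ModelParameters",
    "DimensionalParameters",
    "PlaqueState",
    "PhaseFluxes",
    "nondimensionalise",
    "redimensionalise",
    "source_terms",
    "phase_fluxes",
    "mixture_velocity",
    "boundary_growth_rate",
    "endothelial_value",
    "medial_value",
]

#: Inclusive nondimensional ranges used to warn (not fail) on unusual inputs.
PARAMETER_RANGES = {
    "mu_a": (10.0, 100.0),
    "mu_e": (10.0, 200.0),
    "sigma_e": (0.0, 100.0),
}


@dataclass(frozen=True)
class ModelParameters:
    """Nondimensional rate and transport constants of the plaque model.

    Defaults are the standard nondimensional estimates (reference time one
    week, reference length one macrophage diameter): diffusivities scaled by
    x_S^2/t_S, per-density rates by 1/(N_0 t_S), boundary velocities by
    x_S/t_S.  ``mu_a``, ``mu_e`` and ``sigma_e`` are the biologically variable
    knobs (cell death, efferocytosis, emigration); the default scenario is the
    high-efferocytosis base case mu_a=40, mu_e=60 with no emigration.
    """

    D_f: float = 20.0      # foam-cell random motility
    D_l: float = 200.0     # modLDL diffusivity
    D_c: float = 10.0      # dead-material diffusivity
    chi_l: float = 1000.0  # chemotaxis of foam cells toward modLDL
    chi_c: float = 500.0   # chemotaxis of foam cells toward dead material
    mu_a: float = 40.0     # foam-cell death rate
    mu_e: float = 60.0     # efferocytosis rate (per foam cell per unit dead material)
    mu_p: float = 300.0    # phagocytosis rate (per foam cell per unit modLDL)
    sigma_f: float = 100.0  # monocyte recruitment rate per unit endothelial modLDL
    sigma_l: float = 10.0  # LDL deposition rate
    sigma_e: float = 0.0   # foam-cell egress velocity at the medial boundary

    def __post_init__(self) -> None:
        for fld in fields(self):
            value = getattr(self, fld.name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"ModelParameters.{fld.name} must be finite and >= 0, got {value!r}"
                )

    def replace(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional counterparts (tilded quantities) plus the reference scales.

    ``t_S`` is the reference timescale in seconds (one week by default),
    ``x_S`` the reference length in metres (one macrophage diameter) and
    ``N_0`` the maximum linear phase density in cells per unit ``x_S``.
    Rates carry SI units built from these; they exist only to feed
    :func:`nondimensionalise`.
    """

    D_f: float = 1.0e-14        # m^2/s
    D_l: float = 1.0e-13        # m^2/s
    D_c: float = 5.0e-15        # m^2/s
    chi_l: float = 5.0e-13      # m^2/s per (N_0)
    chi_c: float = 2.5e-13      # m^2/s per (N_0)
    mu_a: float = 6.7e-5        # 1/s
    mu_e: float = 1.0e-4        # 1/(N_0 s)
    mu_p: float = 5.0e-4        # 1/(N_0 s)
    sigma_f: float = 2.7e-9     # m/s
    sigma_l: float = 2.7e-10    # N_0 m/s
    sigma_e: float = 0.0        # m/s
    t_S: float = 6.0e5          # s (one week)
    x_S: float = 1.6e-5         # m (macrophage diameter)
    N_0: float = 1.0            # cells per x_S

    def __post_init__(self) -> None:
        if not (self.t_S > 0 and self.x_S > 0 and self.N_0 > 0):
            raise ValueError("reference scales t_S, x_S, N_0 must be positive")
        for fld in fields(self):
            value = getattr(self, fld.name)
            if not np.isfinite(value):
                raise ValueError(f"DimensionalParameters.{fld.name} must be finite")


def nondimensionalise(dim: DimensionalParameters) -> ModelParameters:
    """Map dimensional parameters to their nondimensional counterparts.

    The rescaling units are: diffusivities by x_S^2/t_S, chemotactic
    coefficients by x_S^2/(N_0 t_S), the death rate by 1/t_S, the per-density
    uptake rates (efferocytosis, phagocytosis) by 1/(N_0 t_S), the boundary
    velocities sigma_f and sigma_e by x_S/t_S, and the LDL deposition rate
    sigma_l by N_0 x_S/t_S.
    """
    t_S, x_S, N_0 = dim.t_S, dim.x_S, dim.N_0
    diff = x_S**2 / t_S
    return ModelParameters(
        D_f=dim.D_f / diff,
        D_l=dim.D_l / diff,
        D_c=dim.D_c / diff,
        chi_l=dim.chi_l / (diff / N_0),
        chi_c=dim.chi_c / (diff / N_0),
        mu_a=dim.mu_a * t_S,
        mu_e=dim.mu_e * N_0 * t_S,
        mu_p=dim.mu_p * N_0 * t_S,
        sigma_f=dim.sigma_f / (x_S / t_S),
        sigma_l=dim.sigma_l / (N_0 * x_S / t_S),
        sigma_e=dim.sigma_e / (x_S / t_S),
    )


def redimensionalise(
    p: ModelParameters, t_S: float, x_S: float, N_0: float
) -> DimensionalParameters:
    """Inverse of :func:`nondimensionalise` for the given reference scales."""
    if not (t_S > 0 and x_S > 0 and N_0 > 0):
        raise ValueError("reference scales t_S, x_S, N_0 must be positive")
    diff = x_S**2 / t_S
    return DimensionalParameters(
        D_f=p.D_f * diff,
        D_l=p.D_l * diff,
        D_c=p.D_c * diff,
        chi_l=p.chi_l * diff / N_0,
        chi_c=p.chi_c * diff / N_0,
        mu_a=p.mu_a / t_S,
        mu_e=p.mu_e / (N_0 * t_S),
        mu_p=p.mu_p / (N_0 * t_S),
        sigma_f=p.sigma_f * x_S / t_S,
        sigma_l=p.sigma_l * N_0 * x_S / t_S,
        sigma_e=p.sigma_e * x_S / t_S,
        t_S=t_S,
        x_S=x_S,
        N_0=N_0,
    )


def endothelial_value(u: np.ndarray) -> float:
    """Second-order extrapolation of a cell-centred field to the y=0 boundary."""
    u = np.asarray(u, dtype=float)
    if u.size == 1:
        return float(u[0])
    return float(1.5 * u[0] - 0.5 * u[1])


def medial_value(u: np.ndarray) -> float:
    """Second-order extrapolation of a cell-centred field to the y=1 boundary."""
    u = np.asarray(u, dtype=float)
    if u.size == 1:
        return float(u[-1])
    return float(1.5 * u[-1] - 0.5 * u[-2])


@dataclass
class PlaqueState:
    """Phase fractions on the normalized grid y = x/R at a single time.

    ``y_grid`` holds cell-centre positions in [0, 1] (endothelium at y=0,
    medial boundary at y=1); ``f``, ``l``, ``c`` are the phase volume
    fractions at those cells, ``R`` the intima width in macrophage diameters
    and ``t`` the time in reference timescales (weeks).
    """

    y_grid: np.ndarray
    f: np.ndarray
    l: np.ndarray
    c: np.ndarray
    R: float
    t: float = 0.0

    @property
    def x(self) -> np.ndarray:
        """Physical cell-centre positions x = y * R."""
        return self.y_grid * self.R

    @property
    def voids_residual(self) -> float:
        """Max-norm deviation from the no-voids condition f + l + c = 1."""
        return float(np.max(np.abs(self.f + self.l + self.c - 1.0)))

    @property
    def l_endo(self) -> float:
        """modLDL fraction at the endothelial boundary x = 0."""
        return endothelial_value(self.l)

    @property
    def f_media(self) -> float:
        """Foam-cell fraction at the medial boundary x = R."""
        return medial_value(self.f)

    def check(self, tol_voids: float = 1e-4, tol_neg: float = 1e-6) -> None:
        """Raise ValueError if the state violates its physical invariants."""
        if self.voids_residual > tol_voids:
            raise ValueError(
                f"no-voids residual {self.voids_residual:.3e} exceeds {tol_voids:.1e}"
            )
        low = min(self.f.min(), self.l.min(), self.c.min())
        if low < -tol_neg:
            raise ValueError(f"negative phase fraction {low:.3e} below -{tol_neg:.1e}")
        # R starts at 1 and can only shrink below it under strong emigration
        # (net influx negative, e.g. sigma_e * f|R > sigma_f * l|0 + sigma_l)
        if self.R <= 0.0:
            raise ValueError(f"domain length R={self.R} must be positive")


@dataclass
class PhaseFluxes:
    """Interphase fluxes, mixture velocity and total fluxes at each node.

    The total fluxes ``j_u = J_u + v u`` are filled in by
    :func:`phase_fluxes`; they are ``None`` if the container was built from
    interphase fluxes alone.
    """

    J_f: np.ndarray
    J_l: np.ndarray
    J_c: np.ndarray
    v: np.ndarray
    j_f: Optional[np.ndarray] = None
    j_l: Optional[np.ndarray] = None
    j_c: Optional[np.ndarray] = None


def source_terms(
    f: np.ndarray | float,
    l: np.ndarray | float,
    c: np.ndarray | float,
    p: ModelParameters,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mass-exchange source terms (s_f, s_l, s_c).

    Phagocytosis converts modLDL to foam-cell volume at rate mu_p*f*l,
    efferocytosis converts dead material at rate mu_e*f*c, and foam cells die
    at rate mu_a*f.  The three terms sum to zero identically (local mass
    conservation).
    """
    f = np.asarray(f, dtype=float)
    l = np.asarray(l, dtype=float)
    c = np.asarray(c, dtype=float)
    phag = p.mu_p * f * l
    effero = p.mu_e * f * c
    death = p.mu_a * f
    s_f = phag + effero - death
    s_l = -phag
    s_c = -effero + death
    return s_f, s_l, s_c


def _interphase_fluxes(
    f: np.ndarray,
    p: ModelParameters,
    df_dx: np.ndarray,
    dl_dx: np.ndarray,
    dc_dx: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    J_f = -p.D_f * df_dx + p.chi_l * f * dl_dx + p.chi_c * f * dc_dx
    J_l = -p.D_l * dl_dx
    J_c = -p.D_c * dc_dx
    return J_f, J_l, J_c


def mixture_velocity(
    state: PlaqueState,
    p: ModelParameters,
    df_dx: np.ndarray,
    dl_dx: np.ndarray,
    dc_dx: np.ndarray,
) -> np.ndarray:
    """Closed-form mixture velocity v(x) implied by the no-voids condition.

    Summing the three continuity equations under f+l+c=1 and integrating from
    the endothelium gives v = sigma_f*l|0 + sigma_l - (J_f + J_l + J_c), i.e.
    the constant material influx at x=0 minus the local interphase flux sum.
    """
    J_f, J_l, J_c = _interphase_fluxes(state.f, p, df_dx, dl_dx, dc_dx)
    v_in = p.sigma_f * state.l_endo + p.sigma_l
    return v_in - (J_f + J_l + J_c)


def phase_fluxes(
    state: PlaqueState,
    p: ModelParameters,
    df_dx: np.ndarray,
    dl_dx: np.ndarray,
    dc_dx: np.ndarray,
) -> PhaseFluxes:
    """Interphase fluxes J_u, mixture velocity v, and total fluxes j_u = J_u + v u.

    Gradients must be taken with respect to the physical coordinate x (on the
    mapped grid, (1/R) d/dy).  The total fluxes satisfy
    j_f + j_l + j_c = sigma_f*l|0 + sigma_l at every node whenever f+l+c = 1:
    the material flux through any cross-section equals the endothelial influx.
    """
    J_f, J_l, J_c = _interphase_fluxes(state.f, p, df_dx, dl_dx, dc_dx)
    v_in = p.sigma_f * state.l_endo + p.sigma_l
    v = v_in - (J_f + J_l + J_c)
    out = PhaseFluxes(J_f=J_f, J_l=J_l, J_c=J_c, v=np.asarray(v, dtype=float))
    out.j_f = J_f + v * state.f
    out.j_l = J_l + v * state.l
    out.j_c = J_c + v * state.c
    return out


def boundary_growth_rate(state: PlaqueState, p: ModelParameters) -> float:
    """Growth rate of the intima width, dR/dt = sigma_f*l|0 + sigma_l - sigma_e*f|R.

    The intima widens by the net volume flux: LDL deposition plus monocyte
    recruitment at the endothelium, minus foam-cell emigration at the media.
    """
    return (
        p.sigma_f * state.l_endo + p.sigma_l - p.sigma_e * state.f_media
    )
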
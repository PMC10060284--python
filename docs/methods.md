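# Methods

## Model

`plaquesim` simulates early atherosclerotic plaque growth as a
one-dimensional multiphase mixture on the moving interval `[0, R(t)]`
between the endothelium (`x = 0`) and the medial boundary (`x = R`).  Three
space-filling phases are tracked as volume fractions: live macrophage foam
cells `f`, modified LDL `l`, and dead cellular material `c`.  Each obeys a
continuity equation

    u_t = -(J_u + v u)_x + s_u ,        u in {f, l, c},

with interphase fluxes

    J_f = -D_f f_x + chi_l f l_x + chi_c f c_x,
    J_l = -D_l l_x,      J_c = -D_c c_x

(random motility plus chemotaxis of foam cells toward modLDL and toward the
find-me signals of dying cells), and mass-exchange kinetics

    s_f = mu_p f l + mu_e f c - mu_a f,
    s_l = -mu_p f l,
    s_c = -mu_e f c + mu_a f

(phagocytosis of modLDL, efferocytic recycling of dead material, cell
death; the three sum to zero identically).  The no-voids closure
`f + l + c = 1` determines the common advective mixture velocity in closed
form,

    v(x) = sigma_f l|_{x=0} + sigma_l - (J_f + J_l + J_c)(x),

and the free boundary moves kinematically with the net volume budget,

    dR/dt = sigma_f l|_{x=0} + sigma_l - sigma_e f|_{x=R}.

Boundary fluxes: LDL deposition `sigma_l` and monocyte recruitment
`sigma_f l|_0` enter at the endothelium; foam cells emigrate into the
lymphatics at the media with egress velocity `sigma_e`; modLDL and dead
material have zero relative flux at the media.  The initial intima is a
uniform layer of resident macrophages (`f = 1`, `R = 1`).

A useful consequence of the closure is that the *total* flux
`j_f + j_l + j_c` is constant in space and equals the endothelial influx
`sigma_f l|_0 + sigma_l`; the package asserts this identity in its tests.
(Note this constant equals `v` only where the interphase fluxes vanish.)

## Parameters

All quantities are nondimensional: lengths in macrophage diameters
(16 µm), times in weeks (6e5 s), densities relative to the close-packed
phase density.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `D_f` | 20 | foam-cell random motility |
| `D_l` | 200 | modLDL diffusivity |
| `D_c` | 10 | dead-material diffusivity |
| `chi_l` | 1000 | chemotaxis toward modLDL |
| `chi_c` | 500 | chemotaxis toward dead material |
| `mu_a` | 40 (range 10–100) | foam-cell death rate |
| `mu_e` | 60 (range 10–200) | efferocytosis rate |
| `mu_p` | 300 | phagocytosis rate |
| `sigma_f` | 100 | monocyte recruitment per unit endothelial modLDL |
| `sigma_l` | 10 | LDL deposition rate |
| `sigma_e` | 0 (range 0–100) | emigration velocity |

`mu_a`, `mu_e` and `sigma_e` are the biological knobs: the
efferocytosis/death ratio `mu_e/mu_a` decides whether the deep plaque
sustains live foam cells, and `sigma_e` decides whether material can leave.
`nondimensionalise` maps dimensional estimates onto these via the
rescalings above (rates by `1/t_S` or `1/(N_0 t_S)`, diffusivities by
`x_S^2/t_S`, boundary velocities by `x_S/t_S`, deposition by
`N_0 x_S/t_S`).

## Deep-plaque characteristic ODE

Away from the endothelium, transport is dominated by bulk advection and
`l ≈ 0`, so the foam-cell fraction along a material characteristic obeys
the logistic-type ODE `dF/dt = mu_e F ((1 - mu_a/mu_e) - F)` with
`C = 1 - F`.  Steady states `F* = 0` and `F* = 1 - mu_a/mu_e` exchange
stability in a transcritical bifurcation at `mu_a = mu_e`; eigenvalues are
`mu_e - mu_a` and `mu_a - mu_e`.  The module ships the closed-form logistic
solution, which serves as an independent oracle for the integrator and
(through the medial density `f|_R`) for the PDE solver.

## Bead tracers

Tagged monocytes are modelled by two volume-less tracer densities: `q_f`
(beads in live cells) and `q_c` (beads in dead material).  Tracers ride
their carrier's total velocity (`J_q = (q/u) J_u`, regularised to zero
where the carrier fraction is below 1e-10), transfer between pools at the
death and efferocytosis rates, enter as a Gaussian endothelial dose of unit
peak and standard deviation 0.035 (~6 h) per tagging time (multiple doses
superpose), and exit only through medial emigration of their live hosts.
The coupling is one-way by construction.  Retention is summarised by
`Q(t) = ∫ (q_f + q_c) dx` and its full width at half maximum
(`circulation_time`), computed with linear interpolation at the half-max
crossings and flagged as right-censored if Q has not fallen below half
maximum by the end of the run.

## Numerics

The moving domain is mapped to `y = x/R ∈ [0, 1]`, giving

    u_t = (1/R) [ y R' u - j_u ]_y - (R'/R) u + s_u ,

which is discretised with a cell-centred finite-volume scheme on a uniform
y-grid (default 200 cells): exact central differences for face gradients,
arithmetic-mean face values (an upwind option exists for high-Péclet
robustness; the two agree to ~1e-3 on default grids), and the physical
boundary *fluxes* imposed directly on the boundary faces — monocyte/LDL
influx and the bead dose at `y = 0`, the emigration flux `sigma_e f|_R`
relative to the moving boundary at `y = 1`.  Boundary values `l|_0` and
`f|_R` are second-order extrapolations from the two nearest cell centres.

This construction was chosen over a node-centred ghost-point closure
because the three endothelial flux conditions become linearly dependent on
the no-voids manifold (the ghost system has determinant `1 - (f+l+c)`),
whereas flux imposition needs no closure solve at all.  Two structural
benefits follow, both verified in the test suite:

* total mass is conserved exactly: `∫ (f+l+c) dx = R(t)` to ~1e-13;
* `f + l + c = 1` is an invariant of the semi-discrete system, so the
  pointwise voids residual sits at the ODE-integrator tolerance (~1e-6
  with the default `rtol=1e-8`) at *every* spatial resolution, rather than
  at the O(h²) truncation level.  Spatial accuracy is therefore measured
  directly: Richardson ratios of solution profiles at 100/200/400 cells
  give the expected factor ≈ 4 per halving of h.

Time integration uses SciPy's BDF with `rtol = 1e-8`, `atol = 1e-10` and an
explicit Jacobian sparsity pattern (block-tridiagonal in the fields, plus
dense couplings through `l|_0`, `f|_R` and `R`), which keeps a
200-cell run under a second on one CPU.  Default snapshot spacing is 0.01,
densified to 5e-4 over `t ∈ [0, 0.06]`: the endothelial modLDL level grows
like `sqrt(t)` immediately after initiation, and finite-difference
diagnostics of `R(t)` need the extra resolution across that ramp (the
derivative estimate *at* `t = 0` itself does not converge — the growth rate
has infinite curvature there — so budget checks are asserted on interior
samples).

Degenerate inputs: phase fractions are never clipped inside the physics
(clipping would break the conservation identities); negativity and voids
are monitored per snapshot, warn beyond `tol_neg = 1e-6` /
`tol_voids = 1e-4` and fail hard at ten times those.  `mu_e = 0` in the
characteristic ODE is treated as pure exponential decay, `mu_a = 0` as
pure logistic growth, and `mu_a = mu_e` reports the single degenerate
steady state.

## Design choices

* **Three evolved phases.** `c` is not eliminated through the constraint;
  preserving `f + l + c = 1` is left to the scheme and monitored, which
  turns the constraint into a free correctness check of the velocity
  closure.
* **Strong emigration can shrink the intima.** With the uniform foam-cell
  initial state and `sigma_e = 80`, `dR/dt(0) = 10 - 80 < 0`; the domain
  contracts below its initial width before stabilising.  The state checks
  therefore require `R > 0`, not `R >= 1`.
* **Preset scenarios** (`fig2_base`, `fig3a`–`d`, `fig8a`–`b`,
  `fig10_beads`, `fig13_beads`) pin the canonical parameter combinations;
  the bead presets use a single dose so that the peak of Q(t) — and hence
  retention fractions and FWHM — are unambiguous.
* **Quadrature** for totals and Q(t) is the midpoint rule on cell
  averages, the rule exact for the finite-volume representation (a uniform
  density `a` integrates to exactly `a R`).

## Test problem sizes and what passing shows

Quantitative assertions (steady-state agreement, conservation, grid
convergence) run at the production resolution of 200–400 cells; trend
assertions (emigration and circulation-time monotonicities) use 100 cells,
where the convergence study shows scalar summaries move by well under 1%.
The model is deterministic throughout — the `seed` field in the solver
config is reserved and inert.

Passing these tests shows that the solver faithfully integrates *this*
idealised mixture model: one spatial dimension, constant diffusivities,
linear chemotaxis, a single lumped death process, no intracellular
cholesterol dynamics, no HDL, and a rigid no-voids closure in place of a
mechanical force balance.  Agreement with the deep-plaque ODE or with the
qualitative behaviour of real plaques (necrotic-core formation, regression
under emigration) is evidence about the model, not about patient tissue.

## Known limitations

* Central face interpolation can oscillate on very coarse grids with the
  default chemotaxis coefficients (`chi_l/D_f = 50`); use `n_cells >= 100`
  or the upwind option.
* Very high emigration (`sigma_e ≈ 80`–100) with beads makes the system
  expensive to integrate (small BDF steps while the domain contracts);
  expect tens of seconds rather than seconds.
* The FWHM circulation time needs the dose window and the decay of Q(t)
  inside the simulated interval; otherwise it is reported as a censored
  lower bound.
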
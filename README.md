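# plaquesim

Free-boundary multiphase simulation of early atherosclerotic plaque
growth.

Early plaques form when low-density lipoprotein (LDL) deposited in the
artery intima is chemically modified, recruits monocytes, and turns the
resulting macrophages into lipid-laden foam cells.  Whether such a lesion
resolves or progresses hinges on three macrophage behaviours that are
impaired in disease: cell death (rate `mu_a`), efferocytic clearance of
dead cells (rate `mu_e`), and emigration into the lymphatics (velocity
`sigma_e`).  `plaquesim` is a simulator for modellers studying this
interplay: it integrates a mass-conservative multiphase mixture model of
the growing intima and reproduces its key predictions — the
efferocytosis/death bifurcation that decides whether the deep plaque keeps
live cells, emigration-driven growth arrest, and the retention of
bead-tagged macrophages.

## Model

Three space-filling phases — foam cells `f`, modLDL `l`, dead material
`c` — evolve on the growing interval `[0, R(t)]` (endothelium to media,
lengths in macrophage diameters, times in weeks):

    u_t = -(J_u + v u)_x + s_u,        f + l + c = 1,

with diffusive/chemotactic interphase fluxes `J_u`, mass-action kinetics
`s_f = mu_p f l + mu_e f c - mu_a f` (and opposite terms in `s_l`, `s_c`),
a mixture velocity fixed in closed form by the no-voids constraint,

    v = sigma_f l|_0 + sigma_l - (J_f + J_l + J_c),

and a kinematic growth law `dR/dt = sigma_f l|_0 + sigma_l - sigma_e f|_R`.
Along deep-plaque characteristics the system reduces to the logistic ODE
`dF/dt = mu_e F (1 - mu_a/mu_e - F)`, whose stable state
`F* = max(0, 1 - mu_a/mu_e)` predicts the medial foam-cell density; a pair
of conserved tracer species models microsphere tagging of monocytes.  See
`docs/methods.md` for the full formulation and numerics.

## Worked example

```python
from plaquesim import (ModelParameters, SolverConfig, simulate,
                       medial_density, steady_states)

params = ModelParameters(mu_a=40.0, mu_e=80.0, sigma_e=0.0)
sol = simulate(params, SolverConfig(n_cells=200, t_end=1.0))

f_R = medial_density(sol, 1.0)
F_star = [s.F for s in steady_states(40.0, 80.0) if s.stability == "stable"][0]
print(f"R(1) = {sol.R[-1]:.3f}")
print(f"f|R(1) = {f_R:.4f}  vs ODE steady state {F_star:.4f}")
print(f"max voids residual = {sol.diagnostics['voids_max'].max():.2e}")
```

prints

```
R(1) = 16.381
f|R(1) = 0.5000  vs ODE steady state 0.5000
max voids residual = 1.15e-06
```

After one week the intima has grown from 1 to ~16 macrophage diameters,
and the foam-cell fraction at the medial boundary has settled onto the
deep-plaque equilibrium `1 - mu_a/mu_e = 0.5`: with efferocytosis twice as
fast as death, half of the deep plaque stays alive.  The voids residual
confirms the three phases still fill space exactly.

The same runs are available from the shell:

```sh
plaquesim simulate --preset fig3c --out out/       # the run above
plaquesim beads --preset fig10_beads --out out/    # bead tagging + t_circ
plaquesim sweep --vary sigma_e=0,20,40,80 --t-end 1 --out out/
plaquesim ode --mu-a 40                            # bifurcation table
plaquesim presets                                  # list scenarios
```

`examples/` contains one short narrative script per capability.

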
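"""Unit and property tests for parameters, nondimensionalisation and pointwise physics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquesim import (
    DimensionalParameters,
    ModelParameters,
    PlaqueState,
    boundary_growth_rate,
    mixture_velocity,
    nondimensionalise,
    phase_fluxes,
    redimensionalise,
    source_terms,
)
from helpers import make_state


class TestNondimensionalisation:
    def test_diffusivity_rescaling(self):
        dim = DimensionalParameters(D_f=1.0e-14, x_S=1.6e-5, t_S=6.0e5)
        p = nondimensionalise(dim)
        assert p.D_f == pytest.approx(23.4375, rel=1e-12)

    def test_death_rate_is_rate_times_timescale(self):
        dim = DimensionalParameters(mu_a=40.0 / 6.0e5)
        assert nondimensionalise(dim).mu_a == pytest.approx(40.0, rel=1e-12)

    def test_ldl_deposition_rescaling(self):
        dim = DimensionalParameters(N_0=1.0, x_S=1.6e-5, t_S=6.0e5,
                                    sigma_l=10.0 * 1.0 * 1.6e-5 / 6.0e5)
        assert nondimensionalise(dim).sigma_l == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize("bad", [{"t_S": 0.0}, {"x_S": -1.0}, {"N_0": 0.0}])
    def test_nonpositive_scales_rejected(self, bad):
        with pytest.raises(ValueError):
            DimensionalParameters(**bad)

    @given(
        scales=st.tuples(
            st.floats(1e2, 1e7), st.floats(1e-7, 1e-3), st.floats(0.1, 10.0)
        ),
        rates=st.lists(st.floats(1e-8, 1e3), min_size=11, max_size=11),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_identity(self, scales, rates):
        """redimensionalise inverts nondimensionalise to 1e-12 relative."""
        t_S, x_S, N_0 = scales
        names = ["D_f", "D_l", "D_c", "chi_l", "chi_c", "mu_a", "mu_e",
                 "mu_p", "sigma_f", "sigma_l", "sigma_e"]
        p = ModelParameters(**dict(zip(names, rates)))
        dim = redimensionalise(p, t_S, x_S, N_0)
        back = nondimensionalise(dim)
        for name in names:
            assert getattr(back, name) == pytest.approx(getattr(p, name), rel=1e-12)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(mu_a=-1.0)


class TestSourceTerms:
    def test_no_foam_cells_no_kinetics(self):
        p = ModelParameters()
        assert source_terms(0.0, 0.3, 0.7, p) == (0.0, 0.0, 0.0)

    def test_coexistence_steady_state_balances(self):
        # f* = 1 - mu_a/mu_e = 0.5 with l = 0: death balances efferocytosis
        p = ModelParameters(mu_a=40.0, mu_e=80.0)
        s_f, s_l, s_c = source_terms(0.5, 0.0, 0.5, p)
        assert s_f == pytest.approx(0.0, abs=1e-14)
        assert s_c == pytest.approx(0.0, abs=1e-14)

    def test_pure_foam_cells_die(self):
        p = ModelParameters(mu_a=40.0)
        s_f, s_l, s_c = source_terms(1.0, 0.0, 0.0, p)
        assert (s_f, s_l, s_c) == (-40.0, 0.0, 40.0)

    @given(
        f=st.floats(0, 1), l=st.floats(0, 1), c=st.floats(0, 1),
        mu_a=st.floats(0, 100), mu_e=st.floats(0, 200), mu_p=st.floats(0, 400),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_local_mass_conservation(self, f, l, c, mu_a, mu_e, mu_p):
        """s_f + s_l + s_c = 0 for any state: mass is only exchanged."""
        p = ModelParameters(mu_a=mu_a, mu_e=mu_e, mu_p=mu_p)
        s_f, s_l, s_c = source_terms(f, l, c, p)
        assert abs(s_f + s_l + s_c) <= 1e-10 * max(1.0, abs(s_f), abs(s_c))


class TestFluxesAndVelocity:
    def test_uniform_pure_foam_state(self):
        """With zero gradients and l|0=0 the only flux is the LDL influx."""
        p = ModelParameters()
        state = make_state(np.ones(8), 0.0, 0.0)
        z = np.zeros(8)
        fx = phase_fluxes(state, p, z, z, z)
        assert np.all(fx.J_f == 0) and np.all(fx.J_l == 0) and np.all(fx.J_c == 0)
        np.testing.assert_allclose(fx.v, p.sigma_l)
        np.testing.assert_allclose(fx.j_f, p.sigma_l)  # advected foam cells

    def test_modldl_diffusive_flux(self):
        p = ModelParameters(D_l=200.0)
        state = make_state(np.full(4, 0.5), 0.25, 0.25)
        z = np.zeros(4)
        fx = phase_fluxes(state, p, z, np.full(4, 0.01), z)
        np.testing.assert_allclose(fx.J_l, -2.0)

    def test_chemotaxis_moves_foam_cells_up_modldl_gradients(self):
        p = ModelParameters(D_f=0.0)
        state = make_state(np.full(4, 0.5), 0.25, 0.25)
        z = np.zeros(4)
        fx = phase_fluxes(state, p, z, np.full(4, 0.01), z)
        assert np.all(fx.J_f > 0)

    def test_velocity_equals_deposition_rate_when_uniform(self):
        p = ModelParameters(sigma_l=10.0)
        state = make_state(np.ones(8), 0.0, 0.0)
        z = np.zeros(8)
        np.testing.assert_allclose(mixture_velocity(state, p, z, z, z), 10.0)

    def test_velocity_includes_monocyte_recruitment(self):
        p = ModelParameters(sigma_f=100.0, sigma_l=10.0)
        state = make_state(np.full(8, 0.95), np.full(8, 0.05), 0.0)
        z = np.zeros(8)
        np.testing.assert_allclose(mixture_velocity(state, p, z, z, z), 15.0)

    def test_no_influx_no_motion(self):
        p = ModelParameters(sigma_f=0.0, sigma_l=0.0)
        state = make_state(np.ones(8), 0.0, 0.0)
        z = np.zeros(8)
        np.testing.assert_allclose(mixture_velocity(state, p, z, z, z), 0.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_total_flux_sum_equals_endothelial_influx(self, seed):
        """j_f + j_l + j_c is constant in x, equal to sigma_f l|0 + sigma_l,
        whenever f + l + c = 1 (the integrated no-voids identity)."""
        rng = np.random.default_rng(seed)
        n = 32
        y = (np.arange(n) + 0.5) / n
        l = 0.2 * np.exp(-5 * y) * rng.uniform(0.5, 1.0)
        c = 0.5 * (1 - np.exp(-3 * y)) * rng.uniform(0.5, 1.0)
        f = 1.0 - l - c
        state = make_state(f, l, c, R=2.0)
        x = y * state.R
        gf, gl, gc = np.gradient(f, x), np.gradient(l, x), np.gradient(c, x)
        p = ModelParameters(mu_e=80.0)
        fx = phase_fluxes(state, p, gf, gl, gc)
        expected = p.sigma_f * state.l_endo + p.sigma_l
        np.testing.assert_allclose(fx.j_f + fx.j_l + fx.j_c, expected, rtol=1e-12)


class TestBoundaryGrowthRate:
    def test_deposition_only(self):
        p = ModelParameters(sigma_e=0.0)
        state = make_state(np.full(4, 0.5), 0.0, 0.5)
        assert boundary_growth_rate(state, p) == pytest.approx(10.0)

    def test_full_balance(self):
        p = ModelParameters(sigma_f=100.0, sigma_l=10.0, sigma_e=20.0)
        state = make_state(np.full(4, 0.5), np.full(4, 0.05), np.full(4, 0.45))
        # sigma_f*0.05 + 10 - 20*0.5 = 5 + 10 - 10
        assert boundary_growth_rate(state, p) == pytest.approx(5.0)

    def test_stabilised_plaque_zero_growth(self):
        p = ModelParameters(sigma_f=100.0, sigma_l=10.0, sigma_e=30.0)
        state = make_state(np.full(4, 0.5), np.full(4, 0.05), np.full(4, 0.45))
        # egress 30*0.5 = 15 = influx 5 + 10
        assert boundary_growth_rate(state, p) == pytest.approx(0.0, abs=1e-12)


class TestPlaqueState:
    def test_voids_residual_and_check(self):
        state = make_state(np.full(4, 0.6), np.full(4, 0.3), np.full(4, 0.1))
        assert state.voids_residual == pytest.approx(0.0, abs=1e-15)
        state.check()

    def test_check_rejects_voids(self):
        state = make_state(np.full(4, 0.5), np.full(4, 0.3), np.full(4, 0.1))
        with pytest.raises(ValueError, match="no-voids"):
            state.check()

    def test_check_rejects_negative_phase(self):
        state = make_state(np.array([0.5, 0.5, 0.5, 0.6]),
                           np.array([0.5, 0.5, 0.5, 0.5]),
                           np.array([0.0, 0.0, 0.0, -0.1]))
        # sums stay at 1 so the negativity check is the one that fires
        with pytest.raises(ValueError, match="negative"):
            state.check()

    def test_x_positions_scale_with_R(self):
        state = make_state(np.ones(4), 0.0, 0.0, R=3.0)
        np.testing.assert_allclose(state.x, state.y_grid * 3.0)
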
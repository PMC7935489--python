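"""Model-core tests: step response, mutation flux, derivatives, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arbisim import (
    ScaledParameters,
    SystemState,
    VariantGrid,
    integrate_episode,
    lysogeny_propensity,
    mutation_operator,
    scaled_derivatives,
)


class TestLysogenyPropensity:
    @pytest.mark.parametrize(
        "phi_max, theta, A, expected",
        [
            (1.0, 0.65, 0.0, 0.0),    # below threshold: fully lytic
            (0.7, 0.0, 0.0, 0.7),     # zero threshold: constant propensity
            (1.0, 0.5, 0.5, 1.0),     # boundary convention: A >= theta switches
            (0.3, 0.2, 0.9, 0.3),
            (0.0, 0.0, 1.0, 0.0),
        ],
    )
    def test_step_response(self, phi_max, theta, A, expected):
        assert lysogeny_propensity(phi_max, theta, A) == expected

    def test_vectorises_over_variants(self):
        phi = lysogeny_propensity(np.array([1.0, 0.5]), np.array([0.2, 0.8]), 0.5)
        assert np.array_equal(phi, [1.0, 0.0])

    @pytest.mark.parametrize("bad", [
        {"phi_max": -0.1, "theta": 0.0, "A": 0.0},
        {"phi_max": 1.5, "theta": 0.0, "A": 0.0},
        {"phi_max": 0.5, "theta": -1.0, "A": 0.0},
        {"phi_max": 0.5, "theta": 0.0, "A": -0.2},
    ])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            lysogeny_propensity(**bad)


class TestMutationOperator:
    def test_zero_rate_is_identity(self, grid441, rng):
        burst = rng.uniform(0, 1, grid441.n_variants)
        out = mutation_operator(burst, grid441, 0.0, 0.0)
        assert np.array_equal(out, burst)

    def test_interior_variant_splits_equally(self):
        grid = VariantGrid.constant_propensity([0.0, 0.1, 0.2])
        burst = np.array([0.0, 1.0, 0.0])
        out = mutation_operator(burst, grid, 0.01, 0.0)
        assert np.allclose(out, [0.005, 0.99, 0.005], atol=1e-15)

    def test_boundary_retains_outward_flux(self):
        grid = VariantGrid.constant_propensity([0.0, 0.1, 0.2])
        out = mutation_operator(np.array([1.0, 0.0, 0.0]), grid, 0.01, 0.0)
        # the boundary variant has a single neighbour: it loses only mu/2
        assert np.allclose(out, [0.995, 0.005, 0.0], atol=1e-15)

    def test_axes_apply_sequentially(self, rng):
        grid = VariantGrid.communication([0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        burst = rng.uniform(0, 2, 9)
        both = mutation_operator(burst, grid, 0.02, 0.03)
        phi_only = mutation_operator(burst, grid, 0.02, 0.0)
        chained = mutation_operator(phi_only, grid, 0.0, 0.03)
        assert np.allclose(both, chained, rtol=1e-14)

    def test_rejects_negative_mass(self, grid101):
        burst = np.zeros(grid101.n_variants)
        burst[0] = -1e-9
        with pytest.raises(ValueError):
            mutation_operator(burst, grid101, 0.01, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        data=st.data(),
        n_phi=st.integers(1, 6),
        n_theta=st.integers(1, 6),
        mu_phi=st.floats(0, 0.5),
        mu_theta=st.floats(0, 0.5),
    )
    def test_conserves_total_mass(self, data, n_phi, n_theta, mu_phi, mu_theta):
        grid = VariantGrid.communication(
            np.linspace(0, 1, n_phi), np.linspace(0, 1, n_theta)
        )
        burst = np.array(data.draw(st.lists(
            st.floats(0, 1e6), min_size=grid.n_variants, max_size=grid.n_variants
        )))
        out = mutation_operator(burst, grid, mu_phi, mu_theta)
        assert out.sum() == pytest.approx(burst.sum(), rel=1e-14, abs=1e-14)
        assert np.all(out >= 0)


def _dimensional_rhs(S, L, P, A, dp, phi_of_A, mutate):
    """Oracle: the dimensional model equations, coded directly.

    dp carries r, K, a, b, B, alpha, delta, u, c.  ``mutate`` applies the
    mutation operator to the per-variant burst vector.
    """
    N = S + L.sum()
    phi = phi_of_A(A)
    logistic = dp.r * (1 - N / dp.K)
    infection = dp.b * dp.a * S * P
    dS = logistic * S - infection.sum()
    dL = logistic * L + phi * infection - dp.alpha * L
    burst = dp.B * dp.alpha * L + dp.B * (1 - phi) * infection
    dP = mutate(burst) - dp.delta * P - dp.a * N * P
    dA = dp.c * infection.sum() - dp.u * N * A
    return dS, dL, dP, dA


class TestScaledDerivatives:
    def test_logistic_only(self, params):
        grid = VariantGrid.single(0.0)
        state = SystemState(s=0.5, l=[0.0], p=[0.0], A=0.0)
        d = scaled_derivatives(state, params, grid)
        assert d.s == pytest.approx(0.25)
        assert d.l[0] == 0 and d.p[0] == 0 and d.A == 0

    def test_arbitrium_production(self, params):
        grid = VariantGrid.single(0.0)
        state = SystemState(s=1.0, l=[0.0], p=[2e-5], A=0.0)
        d = scaled_derivatives(state, params, grid)
        assert d.A == pytest.approx(2e-4, rel=1e-12)

    def test_dimension_mismatch_rejected(self, params, grid101):
        state = SystemState(s=1.0, l=np.zeros(3), p=np.zeros(3), A=0.0)
        with pytest.raises(ValueError):
            scaled_derivatives(state, params, grid101)

    def test_matches_dimensional_oracle(self, rng):
        """The scaled RHS equals the dimensional equations mapped through
        s=S/K, l=L/K, p=bP/K, A->A/(cK), tau=rt, to 1e-12 relative."""
        from arbisim import DimensionalParameters

        dp = DimensionalParameters(r=0.7, K=3e8, a=2.5e-8, b=0.04, B=150.0,
                                   alpha=4e-4, delta=8e-3, u=5e-10, c=2.0)
        grid = VariantGrid.communication([0.0, 0.5, 1.0], [0.0, 0.5])
        mu_phi, mu_theta = 0.013, 0.021
        params = dp.scaled(mu_phi=mu_phi, mu_theta=mu_theta, T=12.0)
        nv = grid.n_variants

        def phi_of_A(A_dim):
            return np.where(A_dim / (dp.c * dp.K) >= grid.theta, grid.phi_max, 0.0)

        def mutate(burst):
            from arbisim import mutation_operator

            return mutation_operator(burst, grid, mu_phi, mu_theta)

        for _ in range(20):
            s = rng.uniform(0, 1)
            l = rng.uniform(0, 0.5, nv)
            p = rng.uniform(0, 2, nv)
            A = rng.uniform(0, 1.2)
            state = SystemState(s=s, l=l, p=p, A=A)
            d = scaled_derivatives(state, params, grid)
            dS, dL, dP, dA = _dimensional_rhs(
                dp.K * s, dp.K * l, dp.K * p / dp.b, dp.c * dp.K * A, dp, phi_of_A, mutate
            )
            scale = dp.r * dp.K
            assert d.s == pytest.approx(dS / scale, rel=1e-12, abs=1e-15)
            np.testing.assert_allclose(d.l, dL / scale, rtol=1e-12, atol=1e-15)
            np.testing.assert_allclose(d.p, dP * dp.b / scale, rtol=1e-12, atol=1e-15)
            assert d.A == pytest.approx(dA / (dp.r * dp.c * dp.K), rel=1e-12, abs=1e-15)


class TestIntegrateEpisode:
    def test_logistic_closed_form(self, params):
        grid = VariantGrid.single(0.0)
        s0 = 0.01
        state = SystemState(s=s0, l=[0.0], p=[0.0], A=0.0)
        traj = integrate_episode(state, params, grid, T=12.0)
        expected = s0 * np.exp(12.0) / (1 + s0 * (np.exp(12.0) - 1))
        assert traj.final_state().s == pytest.approx(expected, abs=1e-8)

    def test_arbitrium_susceptible_conservation(self):
        """Without growth and uptake every lost susceptible cell becomes one
        unit of scaled arbitrium, so A + s is a conserved quantity."""
        params = ScaledParameters(u_hat=1e-12, growth_switch=0)
        grid = VariantGrid.single(0.3)
        state = SystemState(s=1.0, l=[0.0], p=[1e-4], A=0.1)
        traj = integrate_episode(state, params, grid, T=8.0)
        total = traj.s + traj.A
        np.testing.assert_allclose(total, 1.1, atol=1e-8)

    def test_lytic_epidemic_depletes_susceptibles(self, params):
        grid = VariantGrid.single(0.0)
        state = SystemState(s=1.0, l=[0.0], p=[2e-5], A=0.0)
        traj = integrate_episode(state, params, grid, T=12.0)
        assert traj.final_state().s < 1e-3

    def test_states_stay_non_negative(self, params, grid441, rng):
        nv = grid441.n_variants
        state = SystemState(s=1.0, l=np.zeros(nv), p=np.full(nv, 2e-5 / nv), A=0.0)
        traj = integrate_episode(state, params, grid441, T=12.0)
        assert np.all(traj.ys >= 0)

    def test_bacteria_bounded_by_carrying_capacity(self, params):
        grid = VariantGrid.single(0.2)
        state = SystemState(s=0.9, l=[0.05], p=[1e-3], A=0.0)
        traj = integrate_episode(state, params, grid, T=12.0)
        n = traj.s + traj.l.sum(axis=1)
        assert np.all(n <= max(state.n_bacteria, state.k) + 1e-9)

    def test_refinement_stability(self, params):
        grid = VariantGrid.communication([0.0, 1.0], [0.0, 0.6])
        nv = grid.n_variants
        state = SystemState(s=1.0, l=np.zeros(nv), p=np.full(nv, 5e-6), A=0.0)
        base = integrate_episode(state, params, grid, T=12.0, store=False)
        fine = integrate_episode(state, params, grid, T=12.0, store=False,
                                 rtol=5e-9, atol=5e-13)
        y0, y1 = base.ys[-1], fine.ys[-1]
        denom = np.maximum(np.abs(y1), 1e-6)
        assert np.max(np.abs(y0 - y1) / denom) < 1e-6

    def test_matches_scipy_reference(self, params):
        """Same tableau as scipy RK45: endpoint states agree closely."""
        from scipy.integrate import solve_ivp

        from arbisim import _kernels

        grid = VariantGrid.pair((1.0, 0.6), (1.0, 0.65))
        y0 = np.concatenate(([1.0], np.zeros(2), [1e-5, 1e-5], [0.0]))

        def rhs(t, y):
            out = np.empty_like(y)
            _kernels.rhs(y, 1.0, params.B_eff, params.a_hat, params.delta_hat,
                         params.alpha_hat, params.u_hat, 1.0,
                         grid.phi_max, grid.theta, 2, 1, 0.0, 0.0, out)
            return out

        state = SystemState.unpack(y0, 1.0)
        mine = integrate_episode(state, params.replace(mu_phi=0, mu_theta=0),
                                 grid, T=12.0, store=False).ys[-1]
        ref = solve_ivp(rhs, (0, 12.0), y0, method="DOP853",
                        rtol=1e-11, atol=1e-14).y[:, -1]
        np.testing.assert_allclose(mine, ref, rtol=2e-6, atol=1e-12)

    def test_episode_duration_must_be_positive(self, params):
        grid = VariantGrid.single(0.0)
        state = SystemState(s=1.0, l=[0.0], p=[1e-5], A=0.0)
        with pytest.raises(ValueError):
            integrate_episode(state, params, grid, T=0.0)
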
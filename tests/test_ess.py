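"""ESS closed forms, the invasion fixed point, and equilibrium analysis."""

import numpy as np
import pytest

from arbisim import ScaledParameters, SystemState, VariantGrid, integrate_episode
from arbisim import ess


class TestPhiStarClosedForm:
    def test_inoculum_reference_value(self):
        # bB = 2, P0 = 1e-5 K B: (1 - 1/2) / log(1e5)
        value = ess.phi_star_closed_form(b=0.01, B=200, K=1e9, P0=1e-5 * 1e9 * 200)
        assert value == pytest.approx(0.5 / np.log(1e5), rel=1e-12)

    def test_p0_at_saturation_clamps_to_one(self):
        assert ess.phi_star_closed_form(b=0.5, B=10, K=1e9, P0=10 * 1e9) == 1.0

    def test_negative_raw_value_clamped(self):
        # bB < 1: lysogeny never pays, raw expression is negative
        raw = ess.phi_star_closed_form(b=0.001, B=500, K=1e9, P0=1e6, clamp=False)
        assert raw < 0
        assert ess.phi_star_closed_form(b=0.001, B=500, K=1e9, P0=1e6) == 0.0

    def test_monotone_in_p0_and_burst(self):
        base = dict(b=0.01, B=500, K=1e9, P0=1e6)
        v = ess.phi_star_closed_form(**base)
        assert ess.phi_star_closed_form(**{**base, "P0": 1e7}) >= v
        assert ess.phi_star_closed_form(**{**base, "B": 1000}) >= v

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            ess.phi_star_closed_form(b=0.0, B=100, K=1e9, P0=1e6)

    def test_scaled_form_consistent(self):
        b, B, K, P0 = 0.02, 300, 1e9, 2e6
        assert ess.phi_star_scaled(b * B, b * P0 / K) == pytest.approx(
            ess.phi_star_closed_form(b, B, K, P0), rel=1e-12
        )


class TestThetaStarClosedForm:
    @pytest.mark.parametrize("B_eff, expected", [(1.0, 1.0), (2.0, 2 / 3)])
    def test_reference_values(self, B_eff, expected):
        assert ess.theta_star_closed_form(B_eff) == pytest.approx(expected, rel=1e-12)

    def test_high_burst_limit_is_one_half(self):
        assert ess.theta_star_closed_form(1e9) == pytest.approx(0.5, abs=1e-8)

    def test_strictly_decreasing_with_infimum_half(self):
        values = [ess.theta_star_closed_form(B) for B in [0.6, 1, 2, 5, 20, 100, 1e4]]
        assert np.all(np.diff(values) < 0)
        assert values[-1] > 0.5

    def test_domain_error_below_half(self):
        with pytest.raises(ValueError):
            ess.theta_star_closed_form(0.5)


class TestEpidemicDuration:
    def test_increasing_in_resident_propensity(self, params):
        # higher-propensity residents replicate more slowly and collapse the
        # susceptible pool later (above ~0.08 the pool no longer collapses
        # at all at these parameters, which is reported as None)
        TEs = [ess.epidemic_duration(phi, params) for phi in (0.0, 0.02, 0.04)]
        assert all(t is not None for t in TEs)
        assert TEs[0] < TEs[1] < TEs[2]

    def test_larger_inoculum_collapses_sooner(self, params):
        slow = ess.epidemic_duration(0.04, params, p0=1e-5)
        fast = ess.epidemic_duration(0.04, params, p0=1e-3)
        assert fast < slow

    def test_mildly_sensitive_to_collapse_threshold(self, params):
        # s crosses the threshold at a finite speed set by the adsorption
        # rate, so halving the threshold shifts T_E by ln(2)/(a_hat p) —
        # bounded but not negligible
        a = ess.epidemic_duration(0.04, params, p0=1e-4, collapse_eps=1e-3)
        b = ess.epidemic_duration(0.04, params, p0=1e-4, collapse_eps=5e-4)
        assert abs(b - a) / a < 0.1

    def test_no_collapse_reported_as_none(self, params):
        # resident switching to full lysogeny halts the epidemic early
        assert ess.epidemic_duration((1.0, 0.5), params, p0=1e-4) is None


class TestInvaderYield:
    def test_fully_lytic_invader_yields_nothing(self, params):
        traj = ess.resident_background(0.04, params, "phi")
        T_E = ess.epidemic_duration(0.04, params, trajectory=traj)
        assert ess.invader_lysogen_yield(0.0, traj, T_E, params) == 0.0

    def test_matches_nonlinear_rare_invader(self, params):
        """The frozen-background linearisation reproduces a full two-variant
        simulation with the invader at frequency 1e-8, to 0.1%."""
        resident_phi, invader_phi = 0.04, 0.12
        p0 = ess.steady_passaging_p0(resident_phi, params, "phi")
        traj = ess.resident_background(resident_phi, params, "phi", p0=p0)
        T_E = ess.epidemic_duration(resident_phi, params, trajectory=traj)
        linear = ess.invader_lysogen_yield(invader_phi, traj, T_E, params)

        eps = 1e-8 * p0
        grid = VariantGrid.pair((resident_phi, 0.0), (invader_phi, 0.0))
        state = SystemState(s=1.0, l=np.zeros(2), p=[p0, eps], A=0.0)
        two = integrate_episode(
            state, params.replace(mu_phi=0, mu_theta=0), grid, T=T_E,
            rtol=1e-10, atol=1e-16,
        )
        per_capita = two.final_state().l[1] / eps
        assert linear == pytest.approx(per_capita, rel=1e-3)

    def test_requires_covering_trajectory(self, params):
        traj = ess.resident_background(0.04, params, "phi", t_max=1.0)
        with pytest.raises(ValueError):
            ess.invader_lysogen_yield(0.1, traj, 5.0, params)


class TestOptimalInvader:
    def test_short_epidemic_favours_full_lysogeny(self, params):
        traj = ess.resident_background(0.04, params, "phi")
        assert ess.optimal_invader_trait(0.05, params, "phi", traj) == pytest.approx(1.0, abs=0.02)

    def test_optimal_propensity_decreases_with_duration(self, params):
        traj = ess.resident_background(0.04, params, "phi")
        T_E = ess.epidemic_duration(0.04, params, trajectory=traj)
        early = ess.optimal_invader_trait(0.6 * T_E, params, "phi", traj)
        late = ess.optimal_invader_trait(T_E, params, "phi", traj)
        assert late < early


class TestEssFixedPoint:
    def test_phi_axis_matches_simulation_selection(self, params):
        """The fixed point lands on the propensity the full passaging
        simulation selects (0.04 on the standard grid)."""
        res = ess.ess_fixed_point(params, "phi")
        assert res.residual < 1e-3
        assert res.value == pytest.approx(0.04, abs=0.01)
        assert res.T_E > 0

    def test_theta_axis_agrees_with_closed_form_at_high_burst(self, params):
        res = ess.ess_fixed_point(params.replace(B_eff=100.0), "theta")
        assert abs(res.value - ess.theta_star_closed_form(100.0)) < 0.02

    def test_theta_axis_below_closed_form_at_low_burst(self, params):
        res = ess.ess_fixed_point(params, "theta")
        assert res.value < ess.theta_star_closed_form(params.B_eff)

    def test_invasion_stability_in_direct_competition(self, params):
        """Mutants 0.05 away from the fixed-point strategy decline in a
        two-variant serial-passaging competition against it."""
        from arbisim.analysis import competition_experiment
        from arbisim.passaging import PassagingConfig

        phi_ess = ess.ess_fixed_point(params, "phi").value
        cfg = PassagingConfig(n_episodes_max=60, detect_steady_state=False)
        for mutant in (phi_ess - 0.05, phi_ess + 0.05):
            if not 0 <= mutant <= 1:
                continue
            freq = competition_experiment(
                (phi_ess, 0.0), (max(mutant, 0.0), 0.0), 0.05, params, cfg
            )
            assert freq[-1] < 0.05

    def test_unknown_axis_rejected(self, params):
        with pytest.raises(ValueError):
            ess.ess_fixed_point(params, "gamma")


class TestFindEquilibria:
    def test_phage_free_state_always_present(self, params):
        report = ess.find_equilibria(params, 0.04)
        free = report.of_type("phage_free")
        assert len(free) == 1
        np.testing.assert_allclose(free[0].state, [1.0, 0, 0, 0], atol=1e-9)

    def test_default_parameters_give_stable_lysogen_only_state(self, params):
        """At reference parameters the epidemic ends with every susceptible
        cell infected: a stable equilibrium with s = 0 and l, p > 0."""
        report = ess.find_equilibria(params, 0.04)
        lysogen_only = report.of_type("lysogen_only_type_ii")
        assert len(lysogen_only) >= 1
        eq = lysogen_only[0]
        assert eq.stable
        assert eq.state[1] > 0 and eq.state[2] > 0
        # closed-form check: l = 1 - alpha_hat, p = B alpha l / (delta + a l)
        l_exp = 1 - params.alpha_hat
        p_exp = params.B_eff * params.alpha_hat * l_exp / (
            params.delta_hat + params.a_hat * l_exp
        )
        assert eq.state[1] == pytest.approx(l_exp, rel=1e-8)
        assert eq.state[2] == pytest.approx(p_exp, rel=1e-8)

    def test_all_residuals_below_tolerance(self, params):
        report = ess.find_equilibria(params, 0.3)
        assert report.equilibria
        assert all(e.residual < 1e-10 for e in report.equilibria)

    def test_propensity_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            ess.find_equilibria(params, 1.2)
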
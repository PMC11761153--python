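"""Offspring number, equilibria, stability and bifurcation diagnostics."""

import numpy as np
import pytest

from locustdyn import (
    StageState,
    bifurcation_coefficients,
    nontrivial_equilibrium,
    offspring_number_closed_form,
    offspring_number_ngm,
    phi_star,
    rate_aggregates,
    rhs_autonomous,
    stability_report,
)
from locustdyn.threshold import jacobian_autonomous

from conftest import random_valid_params

ORIGIN = StageState(0, 0, 0, 0, 0)


class TestRateAggregates:
    def test_baseline_sums(self, baseline):
        agg = rate_aggregates(baseline)
        assert agg.c1 == pytest.approx(0.4014)
        assert agg.c2 == pytest.approx(0.7595)
        assert agg.c3 == pytest.approx(0.8818)
        assert agg.c4 == pytest.approx(0.2583)
        assert agg.c5 == pytest.approx(0.2611)

    def test_persistence_overrides(self, persistence_params):
        agg = rate_aggregates(persistence_params)
        assert agg.c2 == pytest.approx(0.2763)
        assert agg.c3 == pytest.approx(0.3243)

    def test_zero_losses_leave_development_rates(self, baseline):
        p = baseline.replace(mu_e=0, mu_h=0, mu_b=0, mu_s=0.0001, mu_g=0.0001,
                             beta_1=0, beta_2=0)
        agg = rate_aggregates(p)
        assert agg.c1 == pytest.approx(p.sigma)
        assert agg.c2 == pytest.approx(p.gamma_h)


class TestOffspringNumber:
    def test_zero_fecundity_gives_zero(self, baseline):
        assert offspring_number_closed_form(baseline.replace(phi=0)).N0 == 0.0
        assert offspring_number_ngm(baseline.replace(phi=0)) == pytest.approx(0.0, abs=1e-15)

    def test_decomposition_sums(self, baseline):
        ns = offspring_number_closed_form(baseline)
        assert ns.N0 == pytest.approx(ns.N0S + ns.N0G, rel=1e-15)
        assert ns.N0S >= 0 and ns.N0G >= 0

    def test_extinction_scenario_value(self, extinction_params):
        # closed form and NGM agree; the value sits below the threshold
        ns = offspring_number_closed_form(extinction_params)
        ngm = offspring_number_ngm(extinction_params)
        assert ns.N0 == pytest.approx(ngm, rel=1e-12)
        assert ns.N0 == pytest.approx(0.3624219, rel=1e-6)
        assert ns.N0 < 1

    def test_persistence_scenario_value(self, persistence_params):
        ns = offspring_number_closed_form(persistence_params)
        assert ns.N0 == pytest.approx(offspring_number_ngm(persistence_params), rel=1e-12)
        assert ns.N0 == pytest.approx(14.1864953, rel=1e-6)
        assert ns.N0 > 1

    def test_linear_in_phi_and_female_fraction(self, baseline):
        n1 = offspring_number_closed_form(baseline.replace(phi=2.0)).N0
        n2 = offspring_number_closed_form(baseline.replace(phi=4.0)).N0
        assert n2 == pytest.approx(2 * n1, rel=1e-12)

    def test_independent_of_carrying_capacity(self, baseline):
        a = offspring_number_closed_form(baseline.replace(K=20000)).N0
        b = offspring_number_closed_form(baseline.replace(K=80000)).N0
        assert a == pytest.approx(b, rel=1e-15)

    def test_closed_form_matches_ngm_on_random_draws(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            p = random_valid_params(rng)
            cf = offspring_number_closed_form(p).N0
            ngm = offspring_number_ngm(p)
            assert abs(cf - ngm) < 1e-10 * max(1.0, ngm)

    def test_degenerate_adult_block_rejected(self, baseline):
        with pytest.raises(ValueError, match="degenerate"):
            offspring_number_closed_form(baseline.replace(mu_s=0, mu_g=0))

    def test_monotone_directions_at_baseline(self, baseline):
        # central differences: increasing in recruitment/development rates,
        # decreasing in male ratio and mortalities
        increasing = ("phi", "sigma", "gamma_h", "gamma_b", "psi")
        decreasing = ("eta", "mu_e", "mu_h", "mu_b", "mu_s", "mu_g")
        for name, sign in [(n, +1) for n in increasing] + [(n, -1) for n in decreasing]:
            v = getattr(baseline, name)
            h = 1e-6 * max(abs(v), 1e-3)
            up = offspring_number_closed_form(baseline.replace(**{name: v + h})).N0
            dn = offspring_number_closed_form(baseline.replace(**{name: v - h})).N0
            assert sign * (up - dn) > 0, name


class TestPhiStar:
    def test_offspring_number_is_one_at_threshold(self, baseline):
        ps = phi_star(baseline)
        assert ps > 0
        assert offspring_number_closed_form(baseline.replace(phi=ps)).N0 == pytest.approx(
            1.0, abs=1e-10)

    def test_threshold_on_random_draws(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            p = random_valid_params(rng)
            ps = phi_star(p)
            assert offspring_number_closed_form(p.replace(phi=ps)).N0 == pytest.approx(
                1.0, abs=1e-8)

    def test_doubling_female_fraction_halves_threshold(self, baseline):
        a = phi_star(baseline.replace(eta=0.4))  # female fraction 0.6
        b = phi_star(baseline.replace(eta=0.7))  # female fraction 0.3
        assert a == pytest.approx(b / 2, rel=1e-12)

    def test_vanishing_hatching_guarded(self, baseline):
        with pytest.raises(ValueError):
            phi_star(baseline.replace(sigma=0))


class TestEquilibrium:
    def test_egg_density_identity(self, baseline):
        # N0 = 2 by scaling fecundity to twice the threshold
        p = baseline.replace(phi=2 * phi_star(baseline))
        eq = nontrivial_equilibrium(p)
        assert eq.E == pytest.approx(p.K / 2, rel=1e-9)

    def test_positive_and_zeroes_rhs(self, persistence_params):
        eq = nontrivial_equilibrium(persistence_params)
        assert np.all(eq.to_array() > 0)
        assert np.max(np.abs(rhs_autonomous(eq, persistence_params))) < 1e-9 * persistence_params.K

    def test_residual_on_random_supercritical_draws(self):
        rng = np.random.default_rng(5)
        found = 0
        while found < 40:
            p = random_valid_params(rng)
            if offspring_number_closed_form(p).N0 <= 1.01:
                continue
            found += 1
            eq = nontrivial_equilibrium(p)
            assert np.max(np.abs(rhs_autonomous(eq, p))) < 1e-9 * p.K

    def test_subcritical_rejected(self, extinction_params):
        with pytest.raises(ValueError, match="N0"):
            nontrivial_equilibrium(extinction_params)


class TestStability:
    def test_analytic_jacobian_matches_finite_differences(self, persistence_params):
        p = persistence_params
        y0 = np.array([0.3 * p.K, 0.1 * p.K, 0.05 * p.K, 0.02 * p.K, 0.01 * p.K])
        J = jacobian_autonomous(y0, p)
        Jfd = np.zeros((5, 5))
        h = 1e-4 * p.K
        for j in range(5):
            e = np.zeros(5)
            e[j] = h
            Jfd[:, j] = (rhs_autonomous(y0 + e, p) - rhs_autonomous(y0 - e, p)) / (2 * h)
        assert np.allclose(J, Jfd, rtol=1e-6, atol=1e-8)

    def test_origin_verdicts_match_offspring_number(self, extinction_params,
                                                    persistence_params):
        assert stability_report(extinction_params, ORIGIN).stable
        assert not stability_report(persistence_params, ORIGIN).stable

    def test_origin_verdict_on_random_draws(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = random_valid_params(rng)
            n0 = offspring_number_closed_form(p).N0
            if abs(n0 - 1) < 1e-3:
                continue
            assert stability_report(p, ORIGIN).stable == (n0 < 1)

    def test_positive_equilibrium_is_stable(self, persistence_params):
        eq = nontrivial_equilibrium(persistence_params)
        assert stability_report(persistence_params, eq).stable

    def test_non_equilibrium_point_rejected(self, baseline):
        with pytest.raises(ValueError, match="equilibrium"):
            stability_report(baseline, StageState(0.5 * baseline.K, 0, 0, 100, 100))


class TestBifurcation:
    def test_coefficients_and_forward_classification(self, baseline):
        rep = bifurcation_coefficients(baseline)
        assert rep.phi_star == pytest.approx(phi_star(baseline))
        # Perron-Frobenius: left eigenvector of the Metzler threshold
        # Jacobian is strictly positive, so v1 > 0 and the bifurcation is
        # forward (a < 0 < b)
        assert rep.v1_sign == 1
        assert rep.a < 0 < rep.b
        assert "forward" in rep.classification

    def test_quoted_sign_rule_reported_but_disagrees_at_baseline(self, baseline):
        # (beta_2 mu_s - beta_1 mu_g) = -0.0007 < 0, (c5 - psi c4) > 0:
        # the quoted rule says negative, the actual eigenvector is positive
        rep = bifurcation_coefficients(baseline)
        assert rep.v1_sign_rule == -1
        assert not rep.v1_rule_agrees

    def test_opposite_signs_on_random_draws(self):
        # a = -(2 phi*/K) u1 b with positive phi*, u1, K: a and b always
        # carry opposite signs
        rng = np.random.default_rng(314)
        for _ in range(30):
            p = random_valid_params(rng)
            rep = bifurcation_coefficients(p)
            assert rep.a * rep.b < 0
            assert rep.v1_sign == 1  # Perron-Frobenius positivity

    def test_symmetric_adult_phases_zero_rule_numerator(self, baseline):
        p = baseline.replace(mu_s=0.009, mu_g=0.009, beta_1=0.2, beta_2=0.2)
        rep = bifurcation_coefficients(p)
        assert rep.v1_sign_rule == 0
        assert rep.v1_sign == 1
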
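"""Tests of the analytic rate theory against independent re-derivations."""

import math

import numpy as np
import pytest

from modbalance.gpfm import FitnessParams, malthusian_fitness, solve_initial_traits
from modbalance.theory import (
    clonal_interference_rates,
    desai_fisher_rate,
    discordant_equilibria,
    fdf_in_domain,
    free_recombination_A,
    free_recombination_gamma,
    free_recombination_prediction,
    integrate_rate_model,
    make_rate_model,
    modular_sswm_prediction,
    pleiotropic_sswm_prediction,
)

A = FitnessParams(1.0, 0.5)


class TestDesaiFisherRate:
    @pytest.mark.parametrize(
        "s, Ub, N",
        [(0.01, 1e-5, 1e4), (0.02, 1e-5, 1e4), (0.05, 1e-4, 1e3)],
    )
    def test_matches_independent_evaluation(self, s, Ub, N):
        # independent oracle: assemble the formula from its pieces
        expected = s * s * (2.0 * np.log(N * s) - np.log(s / Ub)) / np.log(s / Ub) ** 2
        assert desai_fisher_rate(s, Ub, N) == pytest.approx(expected, rel=1e-12)

    def test_frozen_values(self):
        assert desai_fisher_rate(0.01, 1e-5, 1e4) == pytest.approx(4.8255e-6, rel=1e-4)
        assert desai_fisher_rate(0.02, 1e-5, 1e4) == pytest.approx(2.0741e-5, rel=1e-4)

    def test_monotone_in_population_size(self):
        rates = [desai_fisher_rate(0.01, 1e-5, N) for N in (1e3, 1e4, 1e5, 1e6)]
        assert rates == sorted(rates)

    def test_domain_predicate(self):
        assert fdf_in_domain(0.01, 1e-5, 1e4)
        assert not fdf_in_domain(0.01, 1e-5, 50)  # Ns < 1
        assert not fdf_in_domain(1e-6, 1e-5, 1e4)  # s < Ub

    def test_rejects_nonpositive_arguments(self):
        with pytest.raises(ValueError):
            desai_fisher_rate(-0.01, 1e-5, 1e4)


class TestPleiotropicPrediction:
    def test_initial_condition(self):
        x0 = (-0.5, -0.7)
        x1, x2 = pleiotropic_sswm_prediction(x0, 0.0, 10_000, 2e-6, 0.1, A)
        assert (x1, x2) == pytest.approx(x0)

    def test_rate_constants(self):
        # beta_i = N U delta^2 / a_i^2 with N=1e4, U=2e-6, delta=0.1
        t = 1.0
        x1, x2 = pleiotropic_sswm_prediction((-1.0, -1.0), t, 10_000, 2e-6, 0.1, A)
        assert -math.log(-x1) == pytest.approx(2e-4)
        assert -math.log(-x2) == pytest.approx(8e-4)

    def test_equal_selection_keeps_ratio_constant(self):
        a_eq = FitnessParams(1.0, 1.0)
        t = np.linspace(0, 1e4, 50)
        x1, x2 = pleiotropic_sswm_prediction((-0.5, -0.4), t, 10_000, 2e-6, 0.1, a_eq)
        assert np.allclose(x2 / x1, 0.8, atol=1e-12)

    def test_gradient_ascent_invariant(self):
        # (x1/x10)^(a1^2) = (x2/x20)^(a2^2) along the prediction
        x0 = solve_initial_traits(-1.39, 1.25, A)
        t = np.linspace(0, 20_000, 100)
        x1, x2 = pleiotropic_sswm_prediction(x0, t, 10_000, 2e-6, 0.1, A)
        lhs = (x1 / x0[0]) ** (A.a1**2)
        rhs = (x2 / x0[1]) ** (A.a2**2)
        assert np.max(np.abs(lhs - rhs)) < 1e-10


class TestModularPrediction:
    def test_halving_time(self):
        # x = x0 / (1 - alpha x0 t): with alpha1=2e-5, x10=-0.5, t=1e5 -> -0.25
        N, mu, delta = 10_000, 5e-9, 0.1
        assert 4 * N * mu * delta / A.a1**2 == pytest.approx(2e-5)
        x1, _, _ = modular_sswm_prediction((-0.5, -0.5), 1e5, N, mu, delta, A)
        assert x1 == pytest.approx(-0.25)

    def test_hyperbola_residual_vanishes(self):
        x0 = solve_initial_traits(-1.39, 0.16, A)
        t = np.linspace(0, 5e5, 200)
        _, _, resid = modular_sswm_prediction(x0, t, 10_000, 5e-9, 0.1, A)
        assert np.max(np.abs(resid)) < 1e-10

    def test_balance_ratio_from_selection_scales(self):
        # the asymptotic line x1/a1^2 = x2/a2^2 has ratio a2^2/a1^2 = 0.25
        assert A.a2**2 / A.a1**2 == pytest.approx(0.25)
        x0 = solve_initial_traits(-1.39, 0.16, A)
        t = np.array([5e7])
        x1, x2, _ = modular_sswm_prediction(x0, t, 10_000, 5e-9, 0.1, A)
        assert x2 / x1 == pytest.approx(0.25, rel=0.02)


class TestClonalInterference:
    def test_balance_line_rate_split(self):
        # on the equal-benefits line s1 = s2: shared-s branch reduces to
        # r2/r1 = |x2|/|x1| exactly
        x = np.array([-0.8, -0.2])
        r = clonal_interference_rates(x, 10_000, 1e-5, 0.1, A)
        assert r[1] / r[0] == pytest.approx(abs(x[1]) / abs(x[0]), rel=1e-10)

    def test_stalling_when_one_module_nearly_exhausted(self):
        # one module at |x| = delta against one far from the optimum: the
        # isolated-rate ratio falls below 1/D and the slow module stalls
        x = np.array([-3.0, -0.1])
        v1 = desai_fisher_rate(2 * 0.1 * 3.0 / A.a1**2, 1e-5 * 3.0 / 0.1, 10_000)
        v2 = desai_fisher_rate(2 * 0.1 * 0.1 / A.a2**2, 1e-5 * 0.1 / 0.1, 10_000)
        assert v2 / v1 < 1.0 / 100.0
        r = clonal_interference_rates(x, 10_000, 1e-5, 0.1, A)
        assert r[1] == 0.0 and r[0] > 0.0

    def test_infinite_threshold_uses_shared_branch_everywhere(self):
        x = np.array([-3.0, -0.1])
        r = clonal_interference_rates(x, 10_000, 1e-5, 0.1, A, D=np.inf)
        assert r[0] > 0.0 and r[1] > 0.0

    def test_balance_line_is_fixed_point_of_ratio_dynamics(self):
        # dR/dt = r1/x1 (r2/r1 - R) = 0 on x2 = (a2^2/a1^2) x1, many depths
        for x1 in np.linspace(-2.0, -0.45, 100):
            x = np.array([x1, 0.25 * x1])
            r = clonal_interference_rates(x, 10_000, 1e-5, 0.1, A)
            dRdt = r[0] / x[0] * (r[1] / r[0] - x[1] / x[0])
            assert abs(dRdt) < 1e-8

    def test_threshold_insensitivity_of_trajectories(self):
        # trajectories for D in {30, 100, 300} agree within 5% in trait space
        x0 = solve_initial_traits(-1.39, 1.25, A)
        paths = []
        for D in (30, 100, 300):
            m = make_rate_model("ci-linked", N=10_000, mu=1e-5, delta=0.1, a=A, D=D)
            tr = integrate_rate_model(m, x0, -0.05, A, rtol=1e-8)
            grid = np.linspace(0, tr.t[-1], 50)
            paths.append(
                np.column_stack([np.interp(grid, tr.t, tr.x1), np.interp(grid, tr.t, tr.x2)])
            )
        for p in paths[1:]:
            rel = np.abs(p - paths[0]) / np.maximum(np.abs(paths[0]), 1e-3)
            assert np.max(rel) < 0.05


class TestFreeRecombination:
    def test_printed_constants(self):
        # gamma_1 = 0.02/log^2(2000), A_1 = log(2000) at N=1e4, mu=1e-5
        assert free_recombination_gamma(1e-5, 0.1, 1.0) == pytest.approx(
            0.02 / math.log(2000.0) ** 2
        )
        assert free_recombination_A(10_000, 1e-5, 1.0) == pytest.approx(math.log(2000.0))

    def test_A_consistent_with_fdf_algebra(self):
        # A_i enters through fDF with s_i/U_bi = 2 delta^2/(mu a_i^2):
        # r_i = fDF * delta / s_i must equal -gamma_i x_i (2 log(-x_i) + A_i)
        N, mu, delta = 10_000, 1e-5, 0.1
        for ai, xi in [(1.0, -0.7), (0.5, -0.3), (1.0, -1.4)]:
            s = 2 * delta * abs(xi) / ai**2
            Ub = mu * abs(xi) / delta
            lhs = desai_fisher_rate(s, Ub, N) * delta / s
            g = free_recombination_gamma(mu, delta, ai)
            Aa = free_recombination_A(N, mu, ai)
            rhs = -g * xi * (2 * math.log(-xi) + Aa)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_initial_condition_and_asymptote(self):
        x0 = solve_initial_traits(-1.39, 1.25, A)
        x1, x2, R, valid = free_recombination_prediction(x0, [0.0, 1e7], 10_000, 1e-5, 0.1, A)
        assert (x1[0], x2[0]) == pytest.approx(x0)
        assert R[-1] == pytest.approx(A.a2 / A.a1, rel=1e-3)

    def test_validity_flags(self):
        x1, x2, R, valid = free_recombination_prediction(
            (-1.0, -1.0), np.linspace(0, 1e5, 20), 10_000, 1e-5, 0.1, A
        )
        assert valid.shape == (2, 20)
        assert valid[:, 0].all()


class TestDiscordantEquilibria:
    TH = (math.pi / 16, 7 * math.pi / 16)

    def test_symmetric_angles_give_modular_balance_ratio(self):
        eq = discordant_equilibria(*self.TH, A)
        assert eq.R1 == pytest.approx(0.19891, abs=1e-4)
        assert eq.R2 == pytest.approx(5.02734, abs=1e-4)
        assert eq.R3 == pytest.approx(0.25)
        assert eq.attractor == pytest.approx(0.25)

    def test_concordant_limit(self):
        eq = discordant_equilibria(0.0, math.pi / 2, A)
        assert eq.R1 == 0.0
        assert eq.R3 == pytest.approx(A.a2**2 / A.a1**2)

    def test_sign_pattern_drives_ratio_to_attractor(self):
        eq = discordant_equilibria(*self.TH, A)
        # below R3 the ratio grows, above R3 it shrinks (x1 < 0 fixed)
        assert eq.rdot(0.21, -0.5, 10_000, 5e-9, 0.1) > 0
        assert eq.rdot(1.0, -0.5, 10_000, 5e-9, 0.1) < 0

    def test_inadmissible_ratio_rejected(self):
        eq = discordant_equilibria(*self.TH, A)
        with pytest.raises(ValueError):
            eq.rdot(6.0, -0.5, 10_000, 5e-9, 0.1)

    def test_equal_angles_rejected(self):
        with pytest.raises(ValueError):
            discordant_equilibria(0.4, 0.4, A)


class TestRateModelIntegration:
    def test_modular_integrator_matches_closed_form(self):
        x0 = solve_initial_traits(-1.39, 1.25, A)
        m = make_rate_model("sswm-modular", N=10_000, mu=5e-9, delta=0.1, a=A)
        tr = integrate_rate_model(m, x0, -0.01, A)
        x1p, x2p, _ = modular_sswm_prediction(x0, tr.t, 10_000, 5e-9, 0.1, A)
        assert np.max(np.abs(tr.x1 - x1p) / np.abs(x1p)) < 1e-6
        assert np.max(np.abs(tr.x2 - x2p) / np.abs(x2p)) < 1e-6

    def test_pleiotropic_integrator_matches_closed_form(self):
        x0 = solve_initial_traits(-1.39, 1.25, A)
        m = make_rate_model("sswm-pleiotropic", N=10_000, mu=5e-9, delta=0.1, a=A, L=200)
        tr = integrate_rate_model(m, x0, -0.01, A)
        x1p, x2p = pleiotropic_sswm_prediction(x0, tr.t, 10_000, 2e-6, 0.1, A)
        assert np.max(np.abs(tr.x1 - x1p) / np.abs(x1p)) < 1e-6
        assert np.max(np.abs(tr.x2 - x2p) / np.abs(x2p)) < 1e-6

    @pytest.mark.parametrize("R0", [0.16, 1.25])
    def test_ci_linked_reaches_and_tracks_balance_line(self, R0):
        x0 = solve_initial_traits(-1.39, R0, A)
        m = make_rate_model("ci-linked", N=10_000, mu=1e-5, delta=0.1, a=A)
        tr = integrate_rate_model(m, x0, -0.02, A)
        # normalized distance to the line x2 = 0.25 x1
        dist = np.abs(tr.x2 - 0.25 * tr.x1) / np.abs(tr.x1)
        hit = np.flatnonzero(dist < 0.02)
        assert hit.size > 0
        after = dist[hit[0] :]
        assert np.all(np.diff(after) <= 1e-10)  # keeps shrinking once on the line

    def test_zero_rate_model_stalls(self):
        m = make_rate_model("sswm-modular", N=10_000, mu=5e-9, delta=0.1, a=A)
        zero = type(m)(regime=m.regime, rate=lambda x: np.zeros(2), params=m.params)
        tr = integrate_rate_model(zero, (-0.5, -0.5), -0.01, A)
        assert tr.stalled
        assert np.allclose(tr.x1, -0.5) and np.allclose(tr.x2, -0.5)

    def test_requires_negative_start(self):
        m = make_rate_model("sswm-modular", N=10_000, mu=5e-9, delta=0.1, a=A)
        with pytest.raises(ValueError):
            integrate_rate_model(m, (0.1, -0.5), -0.01, A)

    def test_discordant_rate_model_confined(self):
        th1, th2 = math.pi / 16, 7 * math.pi / 16
        m = make_rate_model(
            "discordant-sswm", N=10_000, mu=5e-9, delta=0.1, a=A, theta1=th1, theta2=th2
        )
        x0 = solve_initial_traits(-1.39, 1.25, A)
        tr = integrate_rate_model(m, x0, -0.02, A)
        R = tr.x2 / tr.x1
        assert np.all(R >= math.tan(th1) - 1e-6)
        assert np.all(R <= math.tan(th2) + 1e-6)
        # ratio moves monotonically toward the interior equilibrium R3 = 0.25
        assert np.all(np.diff(R) <= 1e-9)
        assert abs(R[-1] - 0.25) < 0.35 * abs(R[0] - 0.25)
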
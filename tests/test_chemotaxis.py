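"""Gradient bias, validity bound and perturbation theory."""

import numpy as np
import pytest

from dictywalk import (
    CouplingParams,
    ModelParams,
    PairState,
    build_direction_coupling,
    build_perturbed_matrix,
    build_transition_matrix,
    closed_form_stationary,
    coupling_coefficient,
    marginal_direction_probs,
    max_valid_epsilon,
    perturbative_stationary,
    solve_stationary,
    stationary_mean_cos,
)
from dictywalk.directions import UNIT_VECTORS, opposite
from dictywalk.markov import STATES


class TestCouplingCoefficient:
    def test_printed_formula_arithmetic(self):
        assert coupling_coefficient(gamma=1.0, L=10.0, C=1.0, grad_c=0.004) == pytest.approx(0.04)

    def test_no_gradient_no_coupling(self):
        assert coupling_coefficient(1.0, 10.0, 5.0, 0.0) == 0.0

    def test_depends_only_on_relative_steepness(self):
        a = coupling_coefficient(0.7, 10.0, 1.0, 0.003)
        b = coupling_coefficient(0.7, 10.0, 2.0, 0.006)
        assert a == pytest.approx(b)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            coupling_coefficient(1.0, 10.0, 0.0, 0.01)

    def test_from_field_constructor(self):
        cp = CouplingParams.from_field(gamma=1.0, C=1.0, grad_c=0.004)
        assert cp.epsilon == pytest.approx(0.04)

    def test_non_unit_gradient_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            CouplingParams(0.01, gradient_direction=(0.0, 2.0))


class TestBiasMatrix:
    def test_rows_sum_to_zero_exactly(self):
        delta = build_direction_coupling()
        # the four biased targets pair as opposite vectors, so exact zero
        assert np.max(np.abs(delta.sum(axis=1))) < 1e-15

    def test_back_step_unbiased(self):
        delta = build_direction_coupling()
        for i, frm in enumerate(STATES):
            j = STATES.index(PairState(frm.curr, opposite(frm.curr)))
            assert delta[i, j] == 0.0

    def test_structural_zeros(self):
        delta = build_direction_coupling()
        for i, frm in enumerate(STATES):
            for j, to in enumerate(STATES):
                if to.prev != frm.curr:
                    assert delta[i, j] == 0.0

    def test_zero_coupling_is_identity_perturbation(self, P0):
        P = build_perturbed_matrix(P0, CouplingParams(0.0))
        assert np.array_equal(P.entries, P0.entries)

    def test_hand_evaluated_biased_entry(self, P0):
        """From (1,2), the de novo target direction 3 gains eps * sqrt(3)/2."""
        frm, to = PairState(1, 2), PairState(2, 3)
        # direction 3 has angle 2pi/3: y-component sqrt(3)/2
        P = build_perturbed_matrix(P0, CouplingParams(0.04))
        gained = P[frm, to] - P0[frm, to]
        assert gained == pytest.approx(0.04 * np.sqrt(3) / 2, abs=1e-15)

    def test_perturbed_rows_still_sum_to_one_exactly(self, P0):
        P = build_perturbed_matrix(P0, CouplingParams(0.04))
        assert np.max(np.abs(P.entries.sum(axis=1) - 1.0)) < 1e-14

    def test_parity_about_gradient_axis(self, P0):
        """Mirror about +y (the gradient) leaves the biased chain invariant."""
        P = build_perturbed_matrix(P0, CouplingParams(0.04)).entries
        refl = {n: (4 - n) % 6 + 1 for n in range(1, 7)}  # theta -> pi - theta
        perm = np.array(
            [STATES.index(PairState(refl[s.prev], refl[s.curr])) for s in STATES]
        )
        assert np.allclose(P[np.ix_(perm, perm)], P, atol=1e-15)

    def test_overlarge_coupling_refused(self, P0):
        with pytest.raises(ValueError, match="bound"):
            build_perturbed_matrix(P0, CouplingParams(0.1))


class TestValidityBound:
    def test_default_parameters_bound_value(self, P0):
        """The binding entry is p/3 = 1/21 against coupling sqrt(3)/2."""
        assert max_valid_epsilon(P0) == pytest.approx(2 / (21 * np.sqrt(3)), rel=1e-12)

    def test_matches_independent_entry_scan(self, P0):
        delta = build_direction_coupling()
        bounds = []
        for i in range(30):
            for j in range(30):
                c = delta[i, j]
                if c < 0:
                    bounds.append(P0.entries[i, j] / -c)
                elif c > 0:
                    bounds.append((1.0 - P0.entries[i, j]) / c)
        assert max_valid_epsilon(P0) == pytest.approx(min(bounds), rel=1e-12)

    def test_monotone_nonincreasing_as_p_decreases(self):
        ps = [0.4, 0.3, 0.2, 1 / 7, 0.1, 0.05, 0.01]
        bounds = [
            max_valid_epsilon(build_transition_matrix(ModelParams(p=p))) for p in ps
        ]
        assert all(b1 >= b2 - 1e-15 for b1, b2 in zip(bounds, bounds[1:]))

    def test_vanishes_with_de_novo_rate(self):
        b = max_valid_epsilon(build_transition_matrix(ModelParams(p=1e-6)))
        assert b < 1e-5


class TestPerturbativeStationary:
    def test_zero_coupling_returns_omega0(self, P0, default_params):
        omega = perturbative_stationary(P0, CouplingParams(0.0))
        assert np.allclose(
            omega.vector, closed_form_stationary(default_params).vector, atol=1e-12
        )

    def test_error_scales_as_epsilon_squared(self, P0):
        eps_grid = [0.005, 0.01, 0.02, 0.04]
        errs = []
        for eps in eps_grid:
            cp = CouplingParams(eps)
            exact = solve_stationary(build_perturbed_matrix(P0, cp))
            approx = perturbative_stationary(P0, cp)
            errs.append(np.max(np.abs(approx.vector - exact.vector)))
        slope = np.polyfit(np.log(eps_grid), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_first_order_error_bounded_by_quadratic(self, P0):
        cp1, cp2 = CouplingParams(0.01), CouplingParams(0.02)
        e = {}
        for cp in (cp1, cp2):
            exact = solve_stationary(build_perturbed_matrix(P0, cp))
            e[cp.epsilon] = np.max(
                np.abs(perturbative_stationary(P0, cp).vector - exact.vector)
            )
        K = e[0.02] / 0.02**2
        assert e[0.01] <= 1.1 * K * 0.01**2


class TestAlignment:
    def test_zero_in_homogeneous_medium(self, default_params):
        for p in (0.1, 1 / 7, 0.5):
            omega = closed_form_stationary(ModelParams(p=p))
            assert stationary_mean_cos(omega) == pytest.approx(0.0, abs=1e-12)

    def test_positive_under_aligned_bias_and_negated_on_reversal(self, P0):
        cp = CouplingParams(0.04)
        exact = solve_stationary(build_perturbed_matrix(P0, cp))
        up = stationary_mean_cos(exact, (0.0, 1.0))
        assert up > 0
        down_cp = CouplingParams(0.04, gradient_direction=(0.0, -1.0))
        exact_down = solve_stationary(build_perturbed_matrix(P0, down_cp))
        assert stationary_mean_cos(exact_down, (0.0, 1.0)) == pytest.approx(-up, abs=1e-12)

    def test_grows_linearly_in_epsilon(self, P0):
        eps_grid = np.array([0.0, 0.01, 0.02, 0.03, 0.04])
        vals = []
        for eps in eps_grid:
            om = (
                solve_stationary(build_perturbed_matrix(P0, CouplingParams(eps)))
                if eps
                else solve_stationary(P0)
            )
            vals.append(stationary_mean_cos(om))
        coeffs = np.polyfit(eps_grid, vals, 1)
        resid = np.array(vals) - np.polyval(coeffs, eps_grid)
        ss_tot = np.sum((vals - np.mean(vals)) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        assert coeffs[0] > 0
        assert r2 > 0.999

    def test_biased_marginals_favor_gradient_directions(self, P0):
        exact = solve_stationary(build_perturbed_matrix(P0, CouplingParams(0.04)))
        marg = marginal_direction_probs(exact)
        # directions 2 and 3 point upward (positive y-component)
        assert marg[1] > 1 / 6 and marg[2] > 1 / 6
        assert marg[4] < 1 / 6 and marg[5] < 1 / 6
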
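"""Exact chain computations: transitions, sojourn counts, costs, fixation."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from evoincentives import (
    EvoParams,
    IncentiveScheme,
    donation_game,
    delta,
    transition_probs,
    expected_visits,
    expected_cost,
    fixation_probabilities,
    cooperation_frequency,
)
from evoincentives.markov_cost import (
    cost_value,
    cost_values,
    fundamental_matrix_dense,
    transition_kernel,
    _visit_vector,
)
from evoincentives.optimizer import theta_min


class TestTransitions:
    def test_neutral_tilt_probabilities(self, dg):
        # theta = -delta makes the Fermi argument zero: both factors are 1/2
        down, stay, up = transition_probs(dg, EvoParams(3, 2.5), 1.9, 1)
        assert (down, stay, up) == pytest.approx((1 / 9, 7 / 9, 1 / 9))

    def test_strong_selection_example(self, dg):
        # beta (delta + theta) = 10 * 0.26 = 2.6
        down, _, up = transition_probs(dg, EvoParams(3, 10.0), 2.16, 1)
        assert up == pytest.approx((2 / 9) / (1 + math.exp(-2.6)), rel=1e-12)
        assert down == pytest.approx((2 / 9) / (1 + math.exp(2.6)), rel=1e-12)

    def test_logistic_saturation_no_overflow(self, dg):
        # theta > -delta and huge beta: downward moves vanish, upward saturate
        N = 8
        for i in (1, 4, 7):
            down, stay, up = transition_probs(dg, EvoParams(N, 1e6), 5.0, i)
            assert down == 0.0
            assert up == pytest.approx((N - i) * i / N**2)
            assert math.isfinite(stay)

    def test_kernel_rows_sum_to_one_and_are_tridiagonal(self, dg2):
        P = transition_kernel(dg2, EvoParams(7, 1.3), 0.8)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P >= 0)
        assert np.allclose(np.triu(P, 2), 0) and np.allclose(np.tril(P, -2), 0)

    def test_state_out_of_range(self, dg):
        with pytest.raises(ValueError, match="transient"):
            transition_probs(dg, EvoParams(3, 1.0), 1.0, 3)


class TestVisits:
    def test_neutral_tilt_hand_inverted_system(self, dg):
        # I - U = [[2/9, -1/9], [-1/9, 2/9]]  =>  n = [[6, 3], [3, 6]]
        for beta in (0.5, 2.0, 10.0):
            v = expected_visits(dg, EvoParams(3, beta), 1.9).visits
            assert v == pytest.approx([4.5, 4.5])

    @pytest.mark.parametrize("N", [3, 7, 20])
    def test_tridiagonal_solvers_match_dense_inverse(self, dg2, N):
        params = EvoParams(N, 1.7)
        theta = 0.9
        Ninv = fundamental_matrix_dense(dg2, params, theta)
        v_dense = 0.5 * (Ninv[0] + Ninv[-1])
        v_banded = _visit_vector(dg2, params, theta)
        assert v_banded == pytest.approx(v_dense, abs=1e-10)
        # batched Thomas path, via the cost it produces
        i = np.arange(1, N)
        e_dense = theta * np.sum(i * v_dense)
        assert cost_values(dg2, params, [theta], "reward")[0] == pytest.approx(e_dense, abs=1e-9)

    @given(N=st.integers(3, 25), beta=st.floats(0, 20), theta=st.floats(0, 10))
    @settings(max_examples=80, deadline=None)
    def test_visits_strictly_positive(self, N, beta, theta):
        game = donation_game(2.0, 1.0)
        v = expected_visits(game, EvoParams(N, beta), theta).visits
        assert np.all(v > 0) and np.all(np.isfinite(v))


class TestCosts:
    def test_neutral_tilt_cost_closed_form(self, dg):
        # at theta = -delta the chain is symmetric: E = N^2 theta H_N = 13.5 theta
        for mode in ("reward", "punishment"):
            res = expected_cost(dg, EvoParams(3, 10.0), IncentiveScheme(mode, 1.9))
            assert res.expected_cost == pytest.approx(13.5 * 1.9)

    def test_schemes_share_visit_profile_and_sum_identity(self, dg2):
        params = EvoParams(9, 2.2)
        theta = 1.4
        er = expected_cost(dg2, params, IncentiveScheme("reward", theta))
        ep = expected_cost(dg2, params, IncentiveScheme("punishment", theta))
        assert er.profile.visits == pytest.approx(ep.profile.visits, rel=1e-14)
        total = theta * params.N * er.profile.visits.sum()
        assert er.expected_cost + ep.expected_cost == pytest.approx(total, rel=1e-12)

    def test_cost_matches_weighted_visit_sum(self, dg2):
        params = EvoParams(6, 0.7)
        res = expected_cost(dg2, params, IncentiveScheme("punishment", 1.3))
        w = params.N - res.profile.states
        assert res.expected_cost == pytest.approx(1.3 * np.sum(w * res.profile.visits))

    def test_batched_grid_matches_scalar_path(self, dg2):
        params = EvoParams(12, 3.0)
        grid = np.linspace(0.05, 6.0, 25)
        batch = cost_values(dg2, params, grid, "punishment")
        scalar = [float(cost_value(dg2, params, t, "punishment").real) for t in grid]
        assert batch == pytest.approx(scalar, rel=1e-12)


class TestFixation:
    def test_neutral_drift_gives_one_over_N(self, dg):
        for N in (3, 11, 40):
            assert fixation_probabilities(dg, EvoParams(N, 0.0), 1.0) == pytest.approx(
                (1 / N, 1 / N))

    def test_symmetric_chain_at_neutral_tilt(self, dg):
        rho_dc, rho_cd = fixation_probabilities(dg, EvoParams(7, 3.0), -delta(dg, 7))
        assert rho_dc == pytest.approx(rho_cd, rel=1e-12)

    def test_fixation_ratio_closed_form_example(self, dg):
        # (N-1)(delta+theta) = 2*(2.9-1.9) = 2 at beta=1: ratio is e^2
        rho_dc, rho_cd = fixation_probabilities(dg, EvoParams(3, 1.0), 2.9)
        assert rho_dc / rho_cd == pytest.approx(math.exp(2), rel=1e-10)

    def test_strong_selection_stays_finite(self, dg):
        # rho_DC saturates to 1 and rho_CD underflows toward 0, but neither
        # overflows or goes NaN
        rho_dc, rho_cd = fixation_probabilities(dg, EvoParams(30, 1e3), 5.0)
        assert 0 < rho_dc <= 1 and 0 <= rho_cd < 1
        assert math.isfinite(rho_dc) and math.isfinite(rho_cd)


class TestCooperationFrequency:
    def test_half_at_neutral_tilt(self, dg):
        assert cooperation_frequency(dg, EvoParams(5, 4.0), -delta(dg, 5)) == pytest.approx(0.5)

    def test_theta_min_inverts_frequency_exactly(self, dg):
        params = EvoParams(6, 2.0)
        for omega in (0.1, 0.5, 0.9, 0.999):
            th0 = theta_min(dg, params, omega)
            assert cooperation_frequency(dg, params, th0) == pytest.approx(omega, abs=1e-12)

    @given(
        N=st.integers(3, 20),
        beta=st.floats(0.01, 5),
        theta=st.floats(0, 8),
        b=st.floats(1.1, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_product_form_equals_closed_exponential(self, N, beta, theta, b):
        """The telescoping product of per-step ratios collapses to one exponential."""
        game = donation_game(b, 1.0)
        x = beta * (delta(game, N) + theta)
        assume(abs(x) * (N - 1) < 500)  # keep the oracle product inside float range
        product = np.prod([(1 + np.exp(x)) / (1 + np.exp(-x)) for _ in range(1, N)])
        rho_dc, rho_cd = fixation_probabilities(game, EvoParams(N, beta), theta)
        assert rho_dc / rho_cd == pytest.approx(product, rel=1e-10)
        closed = 1 / (1 + np.exp(-(N - 1) * x))
        assert cooperation_frequency(game, EvoParams(N, beta), theta) == pytest.approx(
            closed, rel=1e-10)


class TestValidation:
    def test_population_too_small(self):
        with pytest.raises(ValueError, match="N"):
            EvoParams(2, 1.0)

    def test_negative_incentive_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            IncentiveScheme("reward", -0.1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            IncentiveScheme("fine", 1.0)
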
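"""Tridiagonal-inverse machinery, closed-form costs, and asymptotic limits."""

from fractions import Fraction

import numpy as np
import pytest

import coopcost as cc
from coopcost.chain import ChainError, transient_block, transition_matrix
from coopcost.closed_form import (
    logistic_coefficients,
    neutral_P,
    neutral_Q,
    root_pair,
    tridiag_inverse_entry,
    w_matrix,
    yhat,
    yhat_coefficients,
)

# the coefficient table of yhat_0 .. yhat_9 in powers of (bd)
YHAT_TABLE = [
    (1,),
    (1,),
    (1, -1),
    (1, -2),
    (1, -3, 1),
    (1, -4, 3),
    (1, -5, 6, -1),
    (1, -6, 10, -4),
    (1, -7, 15, -10, 1),
    (1, -8, 21, -20, 5),
]


class TestLogisticCoefficients:
    def test_neutral_selection(self):
        co = logistic_coefficients(0.0, -2.0, 1.0)
        assert (co.a_co, co.b_co, co.c_co, co.d_co) == (0.5, 0.5, 0.5, 0.5)

    def test_complementarity(self):
        for beta, delta, theta in [(0.5, -2.0, 1.0), (3.0, -0.3, 2.0)]:
            co = logistic_coefficients(beta, delta, theta)
            assert co.a_co + co.c_co == pytest.approx(1.0, abs=1e-15)
            assert co.b_co + co.d_co == pytest.approx(1.0, abs=1e-15)

    def test_bd_value_and_bound(self):
        co = logistic_coefficients(1.0, -1.0, 0.0)
        assert co.bd == pytest.approx(1.0 / (2.0 + np.e + 1.0 / np.e), rel=1e-12)
        for beta in (0.01, 0.5, 5.0):
            assert logistic_coefficients(beta, -1.3, 0.7).bd < 0.25


class TestYhat:
    @pytest.mark.parametrize("j,expected", list(enumerate(YHAT_TABLE)))
    @pytest.mark.parametrize("method", ["binomial", "recurrence"])
    def test_coefficient_table(self, j, expected, method):
        poly = yhat_coefficients(j, method=method)
        assert poly.coeffs == expected
        assert all(isinstance(m, int) for m in poly.coeffs)

    def test_second_term_closed_form(self):
        # yhat_2 = 1 - bd
        for bd in (0.05, 0.2, 0.24):
            assert yhat(2, bd) == pytest.approx(1.0 - bd, abs=1e-15)

    @pytest.mark.parametrize("bd", [0.01, 0.1, 0.2, 0.24])
    def test_three_evaluators_agree(self, bd):
        for j in range(31):
            vals = [yhat(j, bd, method=m) for m in ("recurrence", "binomial", "roots")]
            assert max(vals) - min(vals) < 1e-12

    def test_positivity_below_quarter(self):
        for bd in np.linspace(0.01, 0.2499, 40):
            for j in range(41):
                assert yhat(j, float(bd)) > 0.0

    def test_exact_rational_evaluation(self):
        val = yhat(9, Fraction(1, 4))
        assert isinstance(val, Fraction)
        assert val == sum(
            m * Fraction(1, 4) ** k for k, m in enumerate(YHAT_TABLE[9])
        )

    def test_empty_matrix_convention(self):
        assert yhat(-1, 0.2) == 0.0

    def test_root_pair_invariants(self):
        for bd in (0.01, 0.1, 0.24):
            r = root_pair(bd)
            assert 0.0 < r.x2 < r.x1 < 1.0
            assert r.x1 + r.x2 == pytest.approx(1.0, abs=1e-15)
            assert r.x1 * r.x2 == pytest.approx(bd, abs=1e-15)
        with pytest.raises(ChainError):
            root_pair(0.3)

    def test_degenerate_root_routed_to_recurrence(self):
        # at bd = 1/4 the root form is 0/0; the recurrence value is returned
        assert yhat(6, 0.25, method="roots") == pytest.approx(
            yhat(6, 0.25, method="recurrence")
        )


class TestWMatrix:
    def test_neutral_three_player(self):
        co = logistic_coefficients(0.0, -2.0, 1.0)
        W = w_matrix(3, 1, co)
        assert np.allclose(W, [[1.0, -0.5], [-0.5, 1.0]])

    def test_factorisation_of_transient_generator(self):
        # I - U_transient = diag{i(N-i)/N^2} W, row by row
        for N in (3, 5, 9):
            for t in range(1, N):
                game = cc.donation_game(N)
                scheme = cc.IncentiveScheme(cc.Kind.REWARD, 1.5, t)
                params = cc.EvolutionParams(N, 0.8)
                co = logistic_coefficients(0.8, game.delta(), 1.5)
                W = w_matrix(N, t, co)
                D = np.diag([i * (N - i) / N**2 for i in range(1, N)])
                V = np.eye(N - 1) - transient_block(
                    transition_matrix(game, scheme, params)
                )
                assert np.allclose(D @ W, V, atol=1e-14)

    def test_full_invest_structure(self):
        # t = N-1: every row is an incentivised (-c, 1, -a) row
        co = logistic_coefficients(1.0, -1.5, 1.0)
        W = w_matrix(5, 4, co)
        assert np.allclose(np.diagonal(W, 1), -co.a_co)
        assert np.allclose(np.diagonal(W, -1), -co.c_co)


class TestTridiagInverse:
    def test_identity(self):
        A = np.eye(6)
        for i in range(6):
            for j in range(6):
                assert tridiag_inverse_entry(A, i, j) == pytest.approx(
                    1.0 if i == j else 0.0
                )

    def test_matches_dense_inverse(self):
        rng = np.random.default_rng(7)
        for n in (2, 5, 12):
            A = (
                np.diag(rng.uniform(2.0, 3.0, n))
                + np.diag(rng.uniform(-1.0, 1.0, n - 1), 1)
                + np.diag(rng.uniform(-1.0, 1.0, n - 1), -1)
            )
            inv = np.linalg.inv(A)
            for i in range(n):
                for j in range(n):
                    assert tridiag_inverse_entry(A, i, j) == pytest.approx(
                        inv[i, j], abs=1e-10
                    )

    def test_neutral_w_entries(self):
        co = logistic_coefficients(0.0, -2.0, 1.0)
        W = w_matrix(3, 1, co)
        assert tridiag_inverse_entry(W, 0, 0) == pytest.approx(4.0 / 3.0)
        assert tridiag_inverse_entry(W, 1, 0) == pytest.approx(2.0 / 3.0)


def cost_grid():
    for N in (3, 4, 6, 9):
        game = cc.donation_game(N)
        for t in (1, 2):
            if t > N - 2:
                continue
            for beta in (1e-3, 0.5, 2.0):
                for theta in (0.0, 0.7, 2.5):
                    for start in cc.Start:
                        yield game, t, beta, theta, start


class TestClosedFormCosts:
    def test_agree_with_fundamental_matrix(self):
        for game, t, beta, theta, start in cost_grid():
            scheme = cc.IncentiveScheme(cc.Kind.REWARD, theta, t)
            params = cc.EvolutionParams(game.N, beta, 0.0, start)
            closed = (
                cc.cost_t1(game, scheme, params)
                if t == 1
                else cc.cost_t2(game, scheme, params)
            )
            matrix = cc.expected_cost(game, scheme, params)
            assert closed == pytest.approx(matrix, rel=1e-9, abs=1e-9)

    def test_zero_incentive(self, dg6):
        params = cc.EvolutionParams(6, 1.0)
        assert cc.cost_t1(dg6, cc.IncentiveScheme(cc.Kind.REWARD, 0.0, 1), params) == 0
        assert cc.cost_t2(dg6, cc.IncentiveScheme(cc.Kind.REWARD, 0.0, 2), params) == 0

    def test_neutral_three_player_reward(self, dg3):
        scheme = cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1)
        val = cc.cost_t1(dg3, scheme, cc.EvolutionParams(3, 1e-6))
        assert val == pytest.approx(4.5, abs=1e-3)

    def test_nonunit_reward_efficiency(self, dg6):
        # E(theta; a) = Etilde(theta / a): halving efficiency doubles the shift
        params = cc.EvolutionParams(6, 1.0)
        direct = cc.cost_t1(
            dg6, cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1, a=0.5), params
        )
        matrix = cc.expected_cost(
            dg6, cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1, a=0.5), params
        )
        assert direct == pytest.approx(matrix, rel=1e-9)

    def test_t2_small_population_routed_to_matrix(self, dg3):
        scheme = cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 2)
        params = cc.EvolutionParams(3, 1.0)
        with pytest.warns(UserWarning, match="full-invest"):
            val = cc.cost_t2(dg3, scheme, params)
        assert val == pytest.approx(cc.expected_cost(dg3, scheme, params))

    def test_punishment_t2_needs_matrix_path(self, dg6):
        scheme = cc.IncentiveScheme(cc.Kind.PUNISHMENT, 1.0, 2)
        with pytest.raises(ChainError, match="matrix path"):
            cc.cost_t2(dg6, scheme, cc.EvolutionParams(6, 1.0))

    def test_wrong_threshold_rejected(self, dg6):
        with pytest.raises(ChainError):
            cc.cost_t1(dg6, cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 2),
                       cc.EvolutionParams(6, 1.0))


class TestDerivative:
    def test_matches_finite_difference(self, dg6):
        h = 1e-5
        for beta in (0.01, 1.0, 5.0):
            for theta in (0.3, 1.0, 3.0):
                for start in (cc.Start.EQUAL, cc.Start.ALLDEF):
                    params = cc.EvolutionParams(6, beta, 0.0, start)
                    d = cc.cost_t1_derivative(
                        dg6, cc.IncentiveScheme(cc.Kind.REWARD, theta, 1), params
                    )
                    f = lambda th: cc.cost_t1(
                        dg6, cc.IncentiveScheme(cc.Kind.REWARD, th, 1), params,
                        precise=True, dps=50,
                    )
                    fd = (f(theta + h) - f(theta - h)) / (2 * h)
                    assert d == pytest.approx(fd, rel=1e-6)
                    assert d > 0.0

    def test_neutral_slope_equals_limit_prefactor(self, dg3):
        # at beta ~ 0 the cost is linear in theta with slope 4.5 (equal start)
        params = cc.EvolutionParams(3, 1e-8)
        d = cc.cost_t1_derivative(
            dg3, cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1), params
        )
        assert d == pytest.approx(4.5, abs=1e-4)

    def test_weighted_start_not_covered(self, dg6):
        with pytest.raises(ChainError):
            cc.cost_t1_derivative(
                dg6,
                cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1),
                cc.EvolutionParams(6, 1.0, 0.0, cc.Start.WEIGHTED),
            )


class TestLimits:
    def test_neutral_components_three_player(self):
        assert neutral_P(3) == Fraction(1)
        assert neutral_Q(3) == Fraction(1)

    def test_neutral_values_three_player(self):
        assert cc.neutral_drift_limit(3, 1.0, cc.Start.EQUAL) == pytest.approx(4.5)
        assert cc.neutral_drift_limit(3, 1.0, cc.Start.ALLDEF) == pytest.approx(6.0)

    def test_weak_selection_converges_to_neutral_limit(self):
        for N in (3, 5, 8):
            game = cc.donation_game(N)
            scheme = cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1)
            for start in (cc.Start.EQUAL, cc.Start.ALLDEF):
                val = cc.cost_t1(game, scheme, cc.EvolutionParams(N, 1e-6, 0.0, start))
                assert val == pytest.approx(
                    cc.neutral_drift_limit(N, 1.0, start), abs=1e-3
                )

    def test_strong_selection_cases(self):
        assert cc.strong_selection_limit(7, 1.0, -1.5) == pytest.approx(49 / 6)
        assert cc.strong_selection_limit(7, 1.0, -1.0) == pytest.approx(2 * 49 / 6)
        assert cc.strong_selection_limit(7, 1.0, -0.5) == np.inf

    def test_strong_selection_convergence(self):
        scheme = cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1)
        game = cc.ConstantGapGame(7, -1.5)
        val = cc.cost_t1(game, scheme, cc.EvolutionParams(7, 50.0))
        assert val == pytest.approx(49 / 6, rel=1e-6)
        knife = cc.cost_t1(
            cc.ConstantGapGame(7, -1.0), scheme, cc.EvolutionParams(7, 50.0)
        )
        assert knife == pytest.approx(2 * 49 / 6, rel=1e-6)

    def test_divergence_above_knife_edge(self):
        scheme = cc.IncentiveScheme(cc.Kind.REWARD, 1.0, 1)
        game = cc.ConstantGapGame(7, -0.5)
        vals = [
            cc.cost_t1(game, scheme, cc.EvolutionParams(7, b)) for b in (10, 20, 40)
        ]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 1e6
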
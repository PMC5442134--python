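"""MSY/MEY analysis: effort bounds, optima, equilibria, viable region."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cprg import (
    GameParams,
    equilibria,
    growth,
    harvest,
    individual_best_response,
    mey,
    msy,
    profitable_effort_bound,
    sustainable_effort_bound,
    viable_fraction,
)
from cprg.yield_analysis import analyze, classification_grid, mey_effort


def sign_change_root(f, lo, hi, n=200_000):
    """Brute-force sign-change search on a fine grid, refined by bisection."""
    xs = np.linspace(lo, hi, n)
    vals = np.array([f(x) for x in xs])
    idx = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    assert idx.size >= 1
    return brentq(f, xs[idx[0]], xs[idx[0] + 1])


class TestSustainableBound:
    def test_zero_at_boundaries(self, params):
        assert sustainable_effort_bound(0.0, params) == 0.0
        assert sustainable_effort_bound(params.N_max, params) == 0.0

    def test_matches_sign_change_of_net_growth(self, params):
        # oracle: where does G(N) - H(X, N) cross zero in X, at N = 500?
        N = 500.0
        root = sign_change_root(
            lambda X: growth(N, params) - harvest(X, N, params), 1.0, 500.0
        )
        assert sustainable_effort_bound(N, params) == pytest.approx(root, rel=1e-9)
        assert root == pytest.approx(130.55, abs=0.01)

    def test_rejects_out_of_range_stock(self, params):
        with pytest.raises(ValueError):
            sustainable_effort_bound(-1.0, params)

    def test_classifies_net_growth_sign(self, params, rng):
        for _ in range(300):
            N = rng.uniform(1.0, params.N_max - 1.0)
            X = rng.uniform(0.1, 2 * params.X_max)
            bound = sustainable_effort_bound(N, params)
            net = growth(N, params) - harvest(X, N, params)
            if abs(X - bound) > 1e-9:
                assert (net > 0) == (X < bound)


class TestProfitableBound:
    def test_matches_sign_change_of_profit(self, params):
        N = 1000.0
        root = sign_change_root(
            lambda X: harvest(X, N, params) - params.c * X, 1.0, 1500.0
        )
        assert profitable_effort_bound(N, params) == pytest.approx(root, rel=1e-9)
        assert root == pytest.approx(709.43, abs=0.01)

    def test_linear_in_stock(self, params, rng):
        for N in rng.uniform(1.0, 500.0, size=20):
            assert profitable_effort_bound(2 * N, params) == pytest.approx(
                2 * profitable_effort_bound(N, params), rel=1e-12
            )

    def test_half_capacity_is_half_the_bound(self, params):
        assert profitable_effort_bound(500.0, params) == pytest.approx(
            profitable_effort_bound(1000.0, params) / 2, rel=1e-12
        )

    def test_decreasing_in_cost(self):
        bounds = [
            profitable_effort_bound(800.0, GameParams(c=c)) for c in (0.2, 0.5, 0.8, 5.0)
        ]
        assert all(b1 > b2 for b1, b2 in zip(bounds, bounds[1:]))

    def test_zero_cost_is_unbounded(self):
        with pytest.raises(ValueError):
            profitable_effort_bound(500.0, GameParams(c=0.0))

    def test_classifies_profit_sign(self, params, rng):
        for _ in range(300):
            N = rng.uniform(1.0, params.N_max)
            X = rng.uniform(0.1, 2 * params.X_max)
            bound = profitable_effort_bound(N, params)
            profit = harvest(X, N, params) - params.c * X
            if abs(X - bound) > 1e-9:
                assert (profit > 0) == (X < bound)


class TestMSY:
    def test_argmax_is_minimum_effort_everywhere(self, params, rng):
        # grid-search oracle: harvest rises with effort, so X_min maximizes
        for N in rng.uniform(0.0, params.N_max, size=10):
            grid = np.linspace(params.X_min, params.X_max, 2001)
            net = np.array([growth(N, params) - harvest(X, N, params) for X in grid])
            X_star, best = msy(N, params)
            assert X_star == params.X_min
            assert best == pytest.approx(net.max(), rel=1e-12, abs=1e-9)

    def test_reference_value_at_half_capacity(self, params):
        _, best = msy(500.0, params)
        assert best == pytest.approx(125.0 - harvest(100.0, 500.0, params), rel=1e-12)
        assert best == pytest.approx(11.2, abs=0.1)

    def test_negative_at_carrying_capacity(self, params):
        _, best = msy(params.N_max, params)
        assert best == pytest.approx(-harvest(params.X_min, params.N_max, params))
        assert best < 0


class TestMEY:
    def test_closed_form_agrees_with_grid_search(self, rng):
        for _ in range(100):
            p = GameParams(
                alpha=rng.uniform(0.05, 0.95),
                beta=rng.uniform(0.05, 1.0),
                c=rng.uniform(0.05, 2.0),
            )
            N = rng.uniform(1.0, p.N_max)
            grid = np.linspace(p.X_min, p.X_max, 4001)
            profit = p.beta * grid**p.alpha * N ** (1 - p.alpha) - p.c * grid
            X_star, best = mey(N, p)
            step = grid[1] - grid[0]
            assert abs(X_star - grid[np.argmax(profit)]) <= step + 1e-9
            assert best >= profit.max() - 1e-6

    def test_interior_argmax_at_capacity(self, params):
        X_star, _ = mey(1000.0, params)
        assert X_star == pytest.approx(141.083, abs=1e-3)

    def test_clips_to_minimum_effort_at_low_stock(self, params):
        X_star, profit = mey(10.0, params)
        assert X_star == params.X_min
        assert profit < 0  # harvesting a collapsed stock loses money

    def test_zero_cost_maximizes_effort(self):
        X_star, _ = mey(500.0, GameParams(c=0.0))
        assert X_star == GameParams().X_max


class TestIndividualBestResponse:
    def test_alone_reduces_to_group_optimum(self, params):
        grid = np.linspace(params.X_min, params.X_max, 401)
        x = individual_best_response(grid, 0.0, 800.0, params)
        X_star, _ = mey(800.0, params)
        assert abs(x - X_star) <= grid[1] - grid[0]

    def test_collapsed_stock_minimizes_cost(self, params):
        grid = np.array([10.0, 20.0, 30.0])
        assert individual_best_response(grid, 90.0, 0.0, params) == 10.0

    def test_ties_break_toward_smaller_action(self, params):
        # N = 0 with zero cost makes every action worth exactly 0
        p = GameParams(c=0.0)
        assert individual_best_response([30.0, 10.0, 20.0], 50.0, 0.0, p) == 10.0

    def test_commons_dilemma_overshoots_fair_share(self, params):
        # when the stock is rich, the selfish best response exceeds the
        # fair share X_e/n of the widest viable effort at the optimal
        # equilibrium — the incentive that erodes the commons
        eq = equilibria(params)
        n = 10
        grid = np.linspace(params.X_min / n, params.X_max / n, 101)
        fair = eq.X_e_range[1] / n
        others = fair * (n - 1)
        best = individual_best_response(grid, others, 800.0, params)
        assert best > fair

    def test_empty_action_set_rejected(self, params):
        with pytest.raises(ValueError):
            individual_best_response([], 0.0, 500.0, params)


class TestEquilibria:
    def test_profitability_equilibrium_closed_form_and_root(self, params):
        eq = equilibria(params)
        closed = params.X_min * (params.c / params.beta) ** (1 / (1 - params.alpha))
        numeric = brentq(
            lambda N: profitable_effort_bound(N, params) - params.X_min, 1.0, 999.0
        )
        assert eq.E_profitable == pytest.approx(closed, rel=1e-12)
        assert eq.E_profitable == pytest.approx(numeric, abs=1e-6)
        assert eq.E_profitable == pytest.approx(141.0, abs=0.1)

    def test_sustainability_equilibria_bracket_the_band(self, params):
        eq = equilibria(params)
        # frozen from a brute-force sign-change oracle on the bound - X_min
        assert eq.E1_sustainable == pytest.approx(63.82, abs=0.05)
        assert eq.E2_sustainable == pytest.approx(563.10, abs=0.05)
        for E in (eq.E1_sustainable, eq.E2_sustainable):
            assert sustainable_effort_bound(E, params) == pytest.approx(
                params.X_min, abs=1e-3
            )

    def test_equilibrium_ordering(self, params):
        eq = equilibria(params)
        assert eq.E1_sustainable < eq.E_profitable < eq.E_optimal < eq.E2_sustainable

    def test_optimal_equilibrium_maximizes_viable_interval(self, params):
        eq = equilibria(params)
        assert eq.E_optimal == pytest.approx(290.6, abs=1.0)
        lo, hi = eq.X_e_range
        assert lo == params.X_min
        assert hi == pytest.approx(
            min(
                sustainable_effort_bound(eq.E_optimal, params),
                profitable_effort_bound(eq.E_optimal, params),
            ),
            rel=1e-9,
        )

    def test_empty_viable_region_detected(self):
        # replenishment too slow to sustain even the minimum effort
        with pytest.raises(ValueError):
            equilibria(GameParams(r_g=0.01))


class TestViableFraction:
    def test_reference_share_of_action_space(self, params):
        assert viable_fraction(params) == pytest.approx(0.0613, abs=0.0005)

    def test_stable_under_grid_refinement(self, params):
        coarse = viable_fraction(params, resolution=1001)
        fine = viable_fraction(params, resolution=2001)
        assert abs(coarse - fine) < 0.001

    def test_low_cost_reduces_to_sustainable_fraction(self):
        # at c = 0.2 the profitable region swallows the sustainable one
        p = GameParams(c=0.2)
        X = np.linspace(p.X_min, p.X_max, 1001)
        N = np.linspace(0.0, p.N_max, 1001)
        XX, NN = np.meshgrid(X, N)
        net = p.r_g * NN * (1 - NN / p.N_max) - p.beta * XX**p.alpha * NN ** (1 - p.alpha)
        # restrict to N > 0: the depleted-stock line is (trivially)
        # sustainable but never profitable, and carries finite grid weight
        sustainable_frac = float(np.mean((net >= 0)[NN > 0]))
        profit = p.beta * XX**p.alpha * NN ** (1 - p.alpha) - p.c * XX
        viable_frac = float(np.mean(((net >= 0) & (profit >= 0))[NN > 0]))
        assert viable_frac == pytest.approx(sustainable_frac, abs=1e-9)
        assert viable_fraction(p, resolution=1001) == pytest.approx(
            sustainable_frac, abs=0.002
        )

    def test_high_cost_shrinks_viability(self):
        assert viable_fraction(GameParams(c=0.8)) < viable_fraction(GameParams(c=0.5))


class TestAnalysisReport:
    def test_report_is_json_serializable_and_complete(self, params):
        import json

        report = analyze(params, n_grid=11)
        text = json.dumps(report)
        assert "equilibria" in text
        assert len(report["grid"]["N"]) == 11
        assert report["viable_fraction"] == pytest.approx(0.0613, abs=0.001)

    def test_classification_grid_shape(self, params):
        df = classification_grid(params, resolution=21)
        assert len(df) == 21 * 21
        assert set(df.columns) >= {"N", "X", "sustainable", "profitable", "viable"}
        assert (df["viable"] == (df["sustainable"] & df["profitable"])).all()
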
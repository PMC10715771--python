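import math

import numpy as np
import pytest

from copeaks import (
    OptimizeParams,
    RRParams,
    draw_random_solution,
    floor_solution,
    run_rr,
    solve_relaxation,
    rounding_success_bound,
)
from copeaks.optimize import budget_cap, objective_cp
from copeaks.rounding import chromosome_rng

from conftest import random_instance


class TestDrawRandomSolution:
    def test_degenerate_probabilities_are_deterministic(self):
        ell_lp = np.array([0.0, 0.0, 1.0, 1.0])
        S = np.ones(4)
        for seed in range(5):
            sol = draw_random_solution(ell_lp, S, 1.0, cap=4, rng=np.random.default_rng(seed))
            np.testing.assert_array_equal(sol.ell, ell_lp)

    def test_binomial_selection_count(self):
        n = 1000
        ell_lp = np.full(n, 0.5)
        rng = np.random.default_rng(0)
        counts = [
            draw_random_solution(ell_lp, np.zeros(n), 0.0, cap=n, rng=rng).n_selected
            for _ in range(10_000)
        ]
        assert abs(np.mean(counts) - 500) < 3 * math.sqrt(n * 0.25)

    def test_objective_recomputed_exactly(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=8)
        sol = draw_random_solution(np.full(8, 0.7), S, 2.0, cap=8, rng=rng)
        assert sol.objective == objective_cp(sol.ell, S, 2.0)


class TestFloorSolution:
    def test_eps_snapping_then_floor(self):
        out = floor_solution(
            np.array([0.2, 1.0, 0.999999999999]), np.zeros(3), 0.0, cap=3, eps=1e-9
        )
        np.testing.assert_array_equal(out.ell, [0, 1, 1])

    def test_integral_input_is_fixed_point(self):
        x = np.array([0.0, 1.0, 1.0, 0.0])
        out = floor_solution(x, np.ones(4), 1.0, cap=4)
        np.testing.assert_array_equal(out.ell, x)

    def test_always_feasible(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            b = float(rng.uniform(0, 1))
            cap = budget_cap(n, b)
            # fractional vectors respecting the budget, as the LP guarantees
            x = rng.uniform(size=n)
            if x.sum() > cap:
                x *= cap / x.sum()
            out = floor_solution(x, np.zeros(n), 1.0, cap=cap)
            assert out.feasible


class TestRunRR:
    def test_zero_iterations_returns_floor(self):
        rel = solve_relaxation(np.array([2.0, 3.0, 1.0]), OptimizeParams(b=0.5, gamma=1.0))
        sol = run_rr(rel, np.array([2.0, 3.0, 1.0]), OptimizeParams(b=0.5, gamma=1.0), RRParams(N=0, seed=0))
        floor = floor_solution(rel.ell_lp, np.array([2.0, 3.0, 1.0]), 1.0, cap=1)
        np.testing.assert_array_equal(sol.ell, floor.ell)

    def test_integral_relaxation_passes_through(self):
        S = np.array([5.0, -1.0, 4.0, -2.0])
        params = OptimizeParams(b=0.5, gamma=0.0)
        rel = solve_relaxation(S, params)
        assert np.all(np.isin(rel.ell_lp, [0.0, 1.0]))
        sol = run_rr(rel, S, params, RRParams(N=20, seed=3))
        np.testing.assert_array_equal(sol.ell, rel.ell_lp)

    def test_sandwich_between_opt_and_floor(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            sv, params = random_instance(rng)
            rel = solve_relaxation(sv, params)
            cap = budget_cap(sv.n, params.b)
            floor = floor_solution(rel.ell_lp, sv, params.gamma, cap)
            sol = run_rr(rel, sv, params, RRParams(N=500, seed=11))
            assert sol.feasible
            assert sol.objective <= floor.objective
            assert sol.objective >= rel.opt_value - 1e-7

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        sv, params = random_instance(rng)
        rel = solve_relaxation(sv, params)
        a = run_rr(rel, sv, params, RRParams(N=100, seed=5))
        b = run_rr(rel, sv, params, RRParams(N=100, seed=5))
        np.testing.assert_array_equal(a.ell, b.ell)

    def test_output_never_violates_budget(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            sv, params = random_instance(rng)
            rel = solve_relaxation(sv, params)
            sol = run_rr(rel, sv, params, RRParams(N=50, seed=1))
            assert sol.n_selected <= budget_cap(sv.n, params.b)

    def test_chromosome_rng_is_order_independent(self):
        a = chromosome_rng(3, "chr1").random(5)
        b = chromosome_rng(3, "chr2").random(5)
        a2 = chromosome_rng(3, "chr1").random(5)
        np.testing.assert_array_equal(a, a2)
        assert not np.array_equal(a, b)


class TestRoundingSuccessBound:
    # frozen spot checks computed independently with 30-digit arithmetic
    SPOT = [
        (10**6, 0.035, 0.05, 1.05, 50, 0.902196666040498478),
        (10**4, 0.035, 0.5, 2.0, 10, 0.998979862041464415),
        (10**5, 0.05, 0.1, 1.5, 25, 0.999949078382764204),
        (5 * 10**5, 0.02, 0.2, 3.0, 5, 0.995884766715931026),
        (10**6, 0.035, 0.05, 1.05, 1, 0.045431556500864734),
    ]

    @pytest.mark.parametrize("n,b,a,c,N,expected", SPOT)
    def test_spot_values(self, n, b, a, c, N, expected):
        assert rounding_success_bound(n, b, a, c, N) == pytest.approx(expected, abs=1e-12)

    def test_zero_iterations_gives_zero(self):
        assert rounding_success_bound(10**6, 0.035, 0.05, 1.05, 0) == 0.0

    def test_monotone_in_N_and_n(self):
        bounds_N = [rounding_success_bound(10**6, 0.035, 0.05, 1.05, N) for N in (1, 5, 25, 125)]
        assert all(x < y for x, y in zip(bounds_N, bounds_N[1:]))
        bounds_n = [rounding_success_bound(n, 0.035, 0.2, 1.5, 10) for n in (10**3, 10**4, 10**5)]
        assert all(x <= y for x, y in zip(bounds_n, bounds_n[1:]))

    def test_failed_hypothesis_returns_vacuous_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert rounding_success_bound(10, 0.035, 0.01, 1.01, 50) == 0.0

    @pytest.mark.parametrize("a,c", [(-1.0, 2.0), (0.0, 2.0), (0.1, 1.0), (0.1, 0.5)])
    def test_invalid_parameters_rejected(self, a, c):
        with pytest.raises(ValueError):
            rounding_success_bound(1000, 0.035, a, c, 10)


class TestExpectationIdentity:
    def test_randomized_lp_objective_is_unbiased_for_opt(self):
        """E[f_LP(ell_rand)] = OPT when the auxiliary coordinates are held at
        their LP-optimal values and only the n decision coordinates are
        Bernoulli-randomized with p_i = ell_i^LP."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            sv, params = random_instance(rng)
            rel = solve_relaxation(sv, params)
            M = 10_000
            draws = rng.random((M, sv.n)) < rel.ell_lp
            f = -(draws @ sv.S) + params.gamma * rel.aux.sum()
            se = f.std(ddof=1) / math.sqrt(M)
            assert abs(f.mean() - rel.opt_value) <= max(4 * se, 1e-9)


class TestRoundingConcentration:
    def test_success_probability_meets_bound(self):
        """Repeated rounding runs on a synthetic instance: the fraction of
        runs producing a candidate set containing a solution with
        n_selected <= nb(1+a) and f - OPT <= (c-1)|OPT| must be at least
        the analytic bound minus 3 binomial standard errors.

        (With OPT <= 0 the literal criterion "f <= c*OPT" would be
        unsatisfiable for c > 1; the multiplicative slack is applied to
        |OPT|, the natural reading of the near-optimality event.)
        """
        from copeaks import generate_synthetic_signals, score

        n, K = 10_000, 5
        blocks = [(1000 * i + 200, 1000 * i + 232, 5.0) for i in range(10)]
        m = generate_synthetic_signals(n, K, blocks, dispersion=0.1, noise=0.5, seed=21)
        sv = score(m)
        params = OptimizeParams()  # b=0.035, gamma=1
        rel = solve_relaxation(sv, params)
        a, c, N, runs = 0.5, 1.05, 50, 40
        bound = rounding_success_bound(n, params.b, a, c, N)
        assert bound > 0.89  # informative regime
        rng = np.random.default_rng(13)
        successes = 0
        for _ in range(runs):
            ok = False
            for _ in range(N):
                draws = rng.random(n) < rel.ell_lp
                n_sel = int(draws.sum())
                if n_sel > n * params.b * (1 + a):
                    continue
                f = objective_cp(draws.astype(float), sv, params.gamma)
                if f - rel.opt_value <= (c - 1.0) * abs(rel.opt_value):
                    ok = True
                    break
            successes += ok
        phat = successes / runs
        se = math.sqrt(max(phat * (1 - phat), 1e-6) / runs)
        assert phat >= bound - 3 * se
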
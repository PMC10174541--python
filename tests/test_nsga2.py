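import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sterilopt.data import DisinfectantKind, apply_scaler, fit_scaler
from sterilopt.models import train_grnn
from sterilopt.nsga2 import (
    GAConfig,
    Scenario,
    crowding_distance,
    evolve,
    fast_non_dominated_sort,
    ideal_point_select,
    nsga2,
    scenario_for,
)
from sterilopt.simulate import make_benchmark_surface


def brute_force_fronts(F, senses):
    """O(n^2 m) dominance oracle: peel non-dominated layers."""
    signs = np.array([1 if s == "min" else -1 for s in senses])
    G = np.asarray(F, float) * signs
    remaining = list(range(len(G)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                np.all(G[j] <= G[i]) and np.any(G[j] < G[i])
                for j in remaining if j != i
            )
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


def sch(X):
    x = X[:, 0]
    return np.column_stack([x ** 2, (x - 2.0) ** 2])


class TestSorting:
    def test_single_point(self):
        fronts = fast_non_dominated_sort(np.array([[1.0, 2.0]]))
        assert len(fronts) == 1 and list(fronts[0]) == [0]

    def test_mutually_nondominating(self):
        F = np.array([[1, 9], [2, 8], [3, 7]], float)
        fronts = fast_non_dominated_sort(F, ("min", "min"))
        assert len(fronts) == 1 and sorted(fronts[0]) == [0, 1, 2]

    def test_empty(self):
        assert fast_non_dominated_sort(np.empty((0, 2))) == []

    @pytest.mark.parametrize("n_obj", [2, 3])
    def test_matches_brute_force_oracle(self, n_obj):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            F = rng.uniform(0, 1, size=(50, n_obj))
            senses = ["min"] * n_obj
            if n_obj == 3:
                senses[1] = "max"
            ours = [sorted(f.tolist()) for f in fast_non_dominated_sort(F, senses)]
            assert ours == brute_force_fronts(F, senses)


class TestCrowding:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(crowding_distance(np.array([[1.0, 2.0]]))))
        assert np.all(np.isinf(crowding_distance(np.array([[1.0, 2.0], [2.0, 1.0]]))))

    def test_evenly_spaced_middle_point(self):
        """Three evenly spaced collinear points: the middle one collects a
        full normalized gap per objective, i.e. distance 2."""
        F = np.array([[0.0, 4.0], [1.0, 2.0], [2.0, 0.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_identical_objectives_zero_interior(self):
        F = np.ones((5, 2))
        d = crowding_distance(F)
        assert np.all(d[~np.isinf(d)] == 0.0)

    def test_boundary_points_get_infinity(self):
        rng = np.random.default_rng(0)
        F = rng.uniform(0, 1, size=(30, 2))
        d = crowding_distance(F)
        boundary = set()
        for k in range(2):
            boundary.add(int(np.argmin(F[:, k])))
            boundary.add(int(np.argmax(F[:, k])))
        assert set(np.flatnonzero(np.isinf(d))) == boundary


class TestIdealPoint:
    def test_hand_arithmetic(self):
        front = np.array([[10.0, 90.0], [5.0, 80.0]])
        assert ideal_point_select(front, m=0.0, n=100.0) == 0  # 14.14 < 20.62

    def test_single_member(self):
        assert ideal_point_select(np.array([[3.0, 50.0]]), 0.0, 100.0) == 0

    def test_utopia_member_selected(self):
        front = np.array([[5.0, 60.0], [1.0, 90.0], [2.0, 70.0]])
        assert ideal_point_select(front, m=1.0, n=90.0) == 1

    def test_tie_break_lower_contamination(self):
        front = np.array([[4.0, 50.0], [2.0, 50.0]])
        # make both equidistant from (3, 50)
        assert ideal_point_select(front, m=3.0, n=50.0) == 1

    def test_empty_front(self):
        with pytest.raises(ValueError):
            ideal_point_select(np.empty((0, 2)), 0.0, 100.0)


class TestEvolve:
    def test_sch_benchmark_front(self):
        res = nsga2(sch, np.array([[-10.0, 10.0]]), GAConfig(generations=200, seed=5))
        xs = res.front_X[:, 0]
        assert np.mean((xs >= -0.05) & (xs <= 2.05)) >= 0.95

    def test_population_stays_in_bounds(self):
        bounds = np.array([[0.0, 3.0], [5.0, 9.0]])
        cfg = GAConfig(population=30, generations=30, mutation_rate=0.5, seed=2)
        res = nsga2(lambda X: X.copy(), bounds, cfg)
        assert np.all(res.population >= bounds[:, 0]) and np.all(res.population <= bounds[:, 1])

    def test_inactive_genes_masked(self):
        bounds = np.array([[0.0, 3.0], [1.0, 2.0], [5.0, 9.0]])
        mask = np.array([True, False, True])
        cfg = GAConfig(population=20, generations=10, mutation_rate=0.5, seed=3)
        res = nsga2(lambda X: X[:, [0, 2]].copy(), bounds, cfg, active_mask=mask)
        assert np.all(res.population[:, 1] == 1.0)

    def test_pure_elitism_fixed_point(self):
        cfg0 = GAConfig(population=20, generations=0, crossover_rate=0.0, mutation_rate=0.0, seed=7)
        cfg5 = GAConfig(population=20, generations=5, crossover_rate=0.0, mutation_rate=0.0, seed=7)
        a = nsga2(sch, np.array([[-10.0, 10.0]]), cfg0)
        b = nsga2(sch, np.array([[-10.0, 10.0]]), cfg5)
        assert np.array_equal(np.sort(a.population, axis=0), np.sort(b.population, axis=0))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            nsga2(sch, np.array([[1.0, -1.0]]), GAConfig(generations=1))

    def test_deterministic(self):
        a = nsga2(sch, np.array([[-10.0, 10.0]]), GAConfig(generations=50, seed=9))
        b = nsga2(sch, np.array([[-10.0, 10.0]]), GAConfig(generations=50, seed=9))
        assert np.array_equal(a.population, b.population)


class TestScenario:
    def test_bounds_from_tested_ranges(self, records):
        sc = scenario_for(DisinfectantKind.H2O2, records)
        assert sc.concentration_bounds == (0.0, 17.5)
        assert sc.time_bounds == (10.0, 20.0)
        assert sc.m == 1.04 and sc.n == 78.12

    def test_inverted_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario(DisinfectantKind.NaOCl, (2.0, 1.0), (5.0, 15.0), 0.0, 100.0)

    def test_front_nondominated_and_ideal_on_front(self, replicated_table, records):
        scaler = fit_scaler(replicated_table.X)
        Xs = apply_scaler(scaler, replicated_table.X)
        cont = train_grnn(Xs, replicated_table.contamination)
        germ = train_grnn(Xs, replicated_table.germination)
        sc = scenario_for(DisinfectantKind.NaOCl, records)
        res = evolve(cont, germ, sc, GAConfig(generations=60, seed=4), scaler=scaler)
        fronts = fast_non_dominated_sort(res.front_F, ("min", "max"))
        assert len(fronts) == 1  # no front member dominates another
        assert any(np.allclose(res.ideal_x, x) for x in res.front_X)
        assert np.all(res.front_X[:, [1, 2, 3, 4, 5]] == 0)  # only NaOCl active

    def test_ideal_distance_history_non_increasing(self, replicated_table, records):
        """(mu+lambda) elitism: the best front distance to the utopia point
        never worsens across generations (seeded run)."""
        scaler = fit_scaler(replicated_table.X)
        Xs = apply_scaler(scaler, replicated_table.X)
        cont = train_grnn(Xs, replicated_table.contamination)
        germ = train_grnn(Xs, replicated_table.germination)
        sc = scenario_for(DisinfectantKind.CaClO2, records)
        res = evolve(cont, germ, sc, GAConfig(generations=150, seed=11), scaler=scaler)
        h = np.asarray(res.history)
        assert np.all(np.diff(h) <= 1e-9)


class TestOptimumRecovery:
    def test_benchmark_ideal_point_recovery(self):
        """On a synthetic surface with known optimum, the GRNN + NSGA-II
        ideal point lands within 10% of each input range."""
        table, surface = make_benchmark_surface("sharp-peak", noise_sd=1.0, seed=0)
        scaler = fit_scaler(table.X)
        Xs = apply_scaler(scaler, table.X)
        cont = train_grnn(Xs, table.contamination)
        germ = train_grnn(Xs, table.germination)
        (clo, chi), (tlo, thi) = surface.bounds
        sc = Scenario(DisinfectantKind.NaOCl, (clo, chi), (tlo, thi),
                      m=float(table.contamination.min()), n=float(table.germination.max()))
        res = evolve(cont, germ, sc, GAConfig(generations=200, seed=1), scaler=scaler)
        assert abs(res.ideal_concentration - surface.ideal_input[0]) <= 0.1 * (chi - clo)
        assert abs(res.ideal_time - surface.ideal_input[1]) <= 0.1 * (thi - tlo)
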
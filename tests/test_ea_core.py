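import numpy as np
import pytest

from grn_evobench.ea_core import (
    DEConfig,
    ESConfig,
    EvalBudget,
    GAConfig,
    MOGAConfig,
    crowding_distance,
    dominates,
    fuzzy_dominance,
    pareto_rank,
    run_de,
    run_es,
    run_moga,
    run_real_ga,
)


def sphere(x):
    return float(np.sum(x**2))


def rosenbrock(x):
    return float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)


BOUNDS10 = np.tile([-5.0, 5.0], (10, 1))
BOUNDS5 = np.tile([-5.0, 5.0], (5, 1))
BOUNDS2 = np.tile([-2.0, 2.0], (2, 1))


class TestBudget:
    def test_counter_contract(self):
        b = EvalBudget(3)
        b.consume()
        b.consume(2)
        assert b.used_calls == 3 and b.remaining == 0
        with pytest.raises(RuntimeError):
            b.consume()

    @pytest.mark.parametrize("budget", [173, 250, 731])
    def test_ga_consumes_budget_exactly(self, budget):
        res = run_real_ga(sphere, BOUNDS5, GAConfig(pop_size=30, budget=budget, seed=0))
        assert res.calls == budget

    def test_es_and_de_consume_budget_exactly(self):
        assert run_es(sphere, BOUNDS5, ESConfig(budget=337, seed=0)).calls == 337
        assert run_de(sphere, BOUNDS2, DEConfig(budget=291, seed=0)).calls == 291
        assert run_moga(lambda x: np.array([sphere(x), sphere(x - 1)]),
                        BOUNDS2, MOGAConfig(pop_size=20, budget=213, seed=0)).calls == 213


class TestOptimisers:
    def test_ga_solves_sphere(self):
        # pilot-calibrated bound: the non-adaptive Gaussian mutation limits
        # final precision to ~1e-2 on the 10-dim sphere at this budget
        res = run_real_ga(sphere, BOUNDS10, GAConfig(pop_size=50, budget=20_000, seed=1))
        assert res.best.fitness < 5e-2

    def test_ga_trace_monotone_and_deterministic(self):
        r1 = run_real_ga(sphere, BOUNDS5, GAConfig(pop_size=20, budget=1000, seed=5))
        r2 = run_real_ga(sphere, BOUNDS5, GAConfig(pop_size=20, budget=1000, seed=5))
        assert r1.trace == r2.trace
        best = [b for _, _, b, _ in r1.trace]
        assert all(b1 >= b2 for b1, b2 in zip(best, best[1:]))

    def test_es_solves_sphere(self):
        res = run_es(sphere, BOUNDS5, ESConfig(budget=5000, seed=1))
        assert res.best.fitness < 1e-3

    def test_es_deterministic(self):
        r1 = run_es(sphere, BOUNDS5, ESConfig(budget=500, seed=2))
        r2 = run_es(sphere, BOUNDS5, ESConfig(budget=500, seed=2))
        assert r1.best.fitness == r2.best.fitness
        np.testing.assert_array_equal(r1.best.genome, r2.best.genome)

    def test_de_solves_rosenbrock(self):
        res = run_de(rosenbrock, BOUNDS2, DEConfig(budget=20_000, seed=1, pop_size=30))
        assert res.best.fitness < 1e-4

    def test_de_best_non_increasing(self):
        res = run_de(rosenbrock, BOUNDS2, DEConfig(budget=2000, seed=3))
        best = [b for _, _, b, _ in res.trace]
        assert all(b1 >= b2 for b1, b2 in zip(best, best[1:]))

    def test_de_degenerate_parameters_stagnate(self):
        # F=0 and CR=0 keep every trial equal to its parent (modulo the one
        # forced crossover coordinate drawn from mutant == a + 0*(b-c))
        res = run_de(sphere, BOUNDS2, DEConfig(budget=400, seed=4, F=0.0, CR=0.0, pop_size=20))
        # population can only be reshuffled among existing coordinate values:
        # best fitness never worsens and genomes stay within initial values
        best = [b for _, _, b, _ in res.trace]
        assert all(b1 >= b2 for b1, b2 in zip(best, best[1:]))

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            run_real_ga(sphere, np.array([[1.0, -1.0]]), GAConfig(pop_size=5, budget=10))


def brute_force_ranks(points):
    """O(n^2 m) repeated-peeling nondominated sorting."""
    n = len(points)
    remaining = set(range(n))
    ranks = np.empty(n, dtype=int)
    r = 0
    while remaining:
        front = {
            i
            for i in remaining
            if not any(dominates(points[j], points[i]) for j in remaining if j != i)
        }
        for i in front:
            ranks[i] = r
        remaining -= front
        r += 1
    return ranks


class TestPareto:
    def test_single_point_rank_zero(self):
        assert pareto_rank([np.array([1.0, 2.0])]).tolist() == [0]

    def test_simple_domination(self):
        assert pareto_rank([np.array([1.0, 1.0]), np.array([2.0, 2.0])]).tolist() == [0, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 100))
        m = int(rng.integers(2, 4))
        pts = [rng.integers(0, 6, m).astype(float) for _ in range(n)]
        np.testing.assert_array_equal(pareto_rank(pts), brute_force_ranks(pts))

    def test_mixed_dimensions_rejected(self):
        with pytest.raises(ValueError):
            pareto_rank([np.array([1.0]), np.array([1.0, 2.0])])


class TestFuzzyDominance:
    def test_self_dominance_is_zero(self):
        u = np.array([1.0, 2.0])
        assert fuzzy_dominance(u, u, np.array([1.0, 1.0])) == 0.0

    def test_full_margin_gives_one(self):
        u, v = np.array([0.0, 0.0]), np.array([2.0, 3.0])
        assert fuzzy_dominance(u, v, np.array([1.0, 1.0])) == 1.0

    def test_partial_advantage(self):
        u, v = np.array([0.0, 1.0]), np.array([1.0, 1.0])
        assert fuzzy_dominance(u, v, np.array([2.0, 2.0])) == pytest.approx(0.25)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_dominance(np.array([0.0]), np.array([1.0]), np.array([0.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_crisp_dominance_implies_positive_degree(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0, 1, 3)
        v = u + rng.uniform(0.01, 1, 3)  # u crisply dominates v
        assert dominates(u, v)
        assert fuzzy_dominance(u, v, np.full(3, 0.5)) > 0
        assert fuzzy_dominance(v, u, np.full(3, 0.5)) == 0


class TestMoga:
    @staticmethod
    def biobjective(x):
        # standard convex two-objective benchmark with a known Pareto set
        return np.array([sphere(x), sphere(x - 1.0)])

    def test_front_is_nondominated_and_budget_exact(self):
        res = run_moga(self.biobjective, BOUNDS2, MOGAConfig(pop_size=30, budget=3000, seed=0))
        assert res.calls == 3000
        objs = [ind.fitness for ind in res.front]
        assert np.all(pareto_rank(objs) == 0)

    def test_deterministic(self):
        r1 = run_moga(self.biobjective, BOUNDS2, MOGAConfig(pop_size=20, budget=600, seed=9))
        r2 = run_moga(self.biobjective, BOUNDS2, MOGAConfig(pop_size=20, budget=600, seed=9))
        np.testing.assert_array_equal(r1.best.genome, r2.best.genome)

    def test_fuzzy_variant_runs_and_converges(self):
        res = run_moga(self.biobjective, BOUNDS2, MOGAConfig(pop_size=30, budget=3000, seed=0, fuzzy=True))
        # knee of f1 = |x|^2, f2 = |x-1|^2 is x = (0.5, 0.5) with f1+f2 = 1
        assert np.sum(res.best.fitness) < 1.05
        np.testing.assert_allclose(res.best.genome, [0.5, 0.5], atol=0.15)

    def test_crowding_distance_boundaries_infinite(self):
        pts = [np.array([0.0, 3.0]), np.array([1.0, 2.0]), np.array([3.0, 0.0])]
        d = crowding_distance(pts)
        assert np.isinf(d[0]) and np.isinf(d[2]) and np.isfinite(d[1])


from hypothesis import given, settings, strategies as st

objective_vectors = st.lists(
    st.lists(st.floats(min_value=0, max_value=10, allow_nan=False),
             min_size=2, max_size=2),
    min_size=1, max_size=20,
)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(points=objective_vectors)
def test_rank_zero_is_exactly_the_nondominated_set(points):
    pts = [np.array(p) for p in points]
    ranks = pareto_rank(pts)
    for i, p in enumerate(pts):
        nondominated = not any(dominates(q, p) for j, q in enumerate(pts) if j != i)
        assert (ranks[i] == 0) == nondominated


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    u=st.lists(st.floats(min_value=0, max_value=10, allow_nan=False), min_size=3, max_size=3),
    v=st.lists(st.floats(min_value=0, max_value=10, allow_nan=False), min_size=3, max_size=3),
)
def test_fuzzy_dominance_bounded_and_antisymmetric(u, v):
    u, v = np.array(u), np.array(v)
    scales = np.ones(3)
    duv = fuzzy_dominance(u, v, scales)
    dvu = fuzzy_dominance(v, u, scales)
    assert 0.0 <= duv <= 1.0 and 0.0 <= dvu <= 1.0
    # advantages are disjoint per objective: both degrees cannot be positive
    # in the same coordinate, so equality forces both to zero
    if np.array_equal(u, v):
        assert duv == dvu == 0.0


def test_trace_csv_roundtrips_through_float_repr(tmp_path):
    from grn_evobench.ea_core import write_trace_csv

    res = run_real_ga(sphere, BOUNDS2, GAConfig(pop_size=10, budget=50, seed=0))
    p = tmp_path / "trace.csv"
    write_trace_csv(res.trace, p)
    lines = p.read_text().strip().splitlines()
    assert lines[0] == "generation,calls,best,median"
    assert len(lines) == len(res.trace) + 1
    g, c, b, m = lines[1].split(",")
    assert (int(g), int(c), float(b), float(m)) == res.trace[0]
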
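"""Shared evolutionary-computation machinery.

Provides the optimisers the inference algorithms are built from — a
real-coded genetic algorithm, a (mu+lambda) evolution strategy with
self-adaptive step sizes, differential evolution (DE/rand/1/bin) — plus
multi-objective selection (fast nondominated sorting, crowding distance,
crisp and fuzzy dominance) and strict function-call budgeting.

Function calls are the currency in which the algorithms are compared, so
budgeting is exact by contract: every objective evaluation increments the
budget by one, optimisers size their final (possibly partial) generation to
land exactly on the budget, and results are deterministic per seed.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EvalBudget",
    "write_trace_csv",
    "Individual",
    "OptimizerResult",
    "GAConfig",
    "ESConfig",
    "DEConfig",
    "MOGAConfig",
    "run_real_ga",
    "run_es",
    "run_de",
    "run_moga",
    "pareto_rank",
    "dominates",
    "fuzzy_dominance",
    "crowding_distance",
]

DIVERGENCE_FITNESS = 1e12


def write_trace_csv(trace, path) -> None:
    """Persist a fitness trace as CSV with columns generation,calls,best,median."""
    lines = ["generation,calls,best,median"]
    lines += [f"{g},{c},{b!r},{m!r}" for g, c, b, m in trace]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class EvalBudget:
    """Strict function-call counter; ``used_calls`` never exceeds ``max_calls``."""

    def __init__(self, max_calls: int):
        if max_calls < 1:
            raise ValueError("budget must be >= 1")
        self.max_calls = int(max_calls)
        self.used_calls = 0

    @property
    def remaining(self) -> int:
        return self.max_calls - self.used_calls

    def consume(self, k: int = 1) -> None:
        if self.used_calls + k > self.max_calls:
            raise RuntimeError("function-call budget overrun")
        self.used_calls += k


@dataclasses.dataclass
class Individual:
    genome: np.ndarray
    fitness: float | np.ndarray | None = None

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None


@dataclasses.dataclass
class OptimizerResult:
    best: Individual
    trace: list[tuple[int, int, float, float]]  # (generation, calls, best, median)
    calls: int
    population: list[Individual]
    front: list[Individual] | None = None  # final nondominated set (MO only)


def _check_bounds(bounds: np.ndarray) -> np.ndarray:
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("bounds must be a (dim, 2) array with lo <= hi")
    return bounds


# ---------------------------------------------------------------------------
# Single-objective optimisers


@dataclasses.dataclass
class GAConfig:
    pop_size: int = 50
    budget: int = 10_000
    seed: int = 0
    crossover_prob: float = 0.9
    blx_alpha: float = 0.5
    mutation_sigma_frac: float = 0.05  # Gaussian sigma as fraction of range
    mutation_prob: float | None = None  # default 1/dim
    tournament_size: int = 2
    n_elite: int = 1


def run_real_ga(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    cfg: GAConfig,
    budget: EvalBudget | None = None,
    init_population: np.ndarray | None = None,
) -> OptimizerResult:
    """Generational real-coded GA with tournament selection, BLX-alpha
    crossover, per-coordinate Gaussian mutation and elitism.

    Runs until the function-call budget is exhausted exactly (the last
    generation is truncated if needed); the best-so-far trace is monotone
    non-increasing by elitism.
    """
    bounds = _check_bounds(bounds)
    dim = bounds.shape[0]
    rng = np.random.default_rng(cfg.seed)
    budget = budget or EvalBudget(cfg.budget)
    if budget.max_calls < cfg.pop_size:
        raise ValueError("budget must cover at least one full population")
    p_mut = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / dim
    span = bounds[:, 1] - bounds[:, 0]

    if init_population is None:
        genomes = rng.uniform(bounds[:, 0], bounds[:, 1], size=(cfg.pop_size, dim))
    else:
        genomes = np.array(init_population, dtype=float)
    pop = [Individual(g) for g in genomes]
    for ind in pop:
        budget.consume()
        ind.fitness = float(objective(ind.genome))

    trace = []
    gen = 0
    _record(trace, gen, budget, pop)
    while budget.remaining > 0:
        gen += 1
        order = np.argsort([ind.fitness for ind in pop], kind="stable")
        elites = [Individual(pop[i].genome.copy(), pop[i].fitness) for i in order[: cfg.n_elite]]
        n_children = min(cfg.pop_size - cfg.n_elite, budget.remaining)
        children = []
        for _ in range(n_children):
            p1 = _tournament(pop, rng, cfg.tournament_size)
            p2 = _tournament(pop, rng, cfg.tournament_size)
            child = _blx_crossover(p1.genome, p2.genome, cfg, rng) if rng.random() < cfg.crossover_prob else p1.genome.copy()
            mask = rng.random(dim) < p_mut
            child[mask] += rng.normal(0.0, cfg.mutation_sigma_frac * span[mask])
            child = np.clip(child, bounds[:, 0], bounds[:, 1])
            ind = Individual(child)
            budget.consume()
            ind.fitness = float(objective(child))
            children.append(ind)
        pop = elites + children
        _record(trace, gen, budget, pop)
    best = min(pop, key=lambda ind: ind.fitness)
    return OptimizerResult(best=best, trace=trace, calls=budget.used_calls, population=pop)


def _tournament(pop: list[Individual], rng: np.random.Generator, k: int) -> Individual:
    idx = rng.integers(0, len(pop), size=k)
    return min((pop[i] for i in idx), key=lambda ind: ind.fitness)


def _blx_crossover(a: np.ndarray, b: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    d = (hi - lo) * cfg.blx_alpha
    return rng.uniform(lo - d, hi + d)


def _record(trace, gen, budget, pop):
    fits = np.array([float(np.sum(ind.fitness)) for ind in pop])
    prev_best = trace[-1][2] if trace else np.inf
    trace.append((gen, budget.used_calls, min(prev_best, float(fits.min())), float(np.median(fits))))


@dataclasses.dataclass
class ESConfig:
    mu: int = 10
    lam: int = 40
    budget: int = 5_000
    seed: int = 0
    sigma_init_frac: float = 0.1  # initial step as fraction of range
    sigma_floor: float = 1e-12


def run_es(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    cfg: ESConfig,
    budget: EvalBudget | None = None,
    init_parents: np.ndarray | None = None,
) -> OptimizerResult:
    """(mu + lambda) evolution strategy with log-normal self-adaptive
    per-coordinate step sizes; mutation only, no crossover.

    ``init_parents`` optionally supplies genomes for the first parents
    (e.g. a warm start); remaining parents are random.
    """
    bounds = _check_bounds(bounds)
    dim = bounds.shape[0]
    rng = np.random.default_rng(cfg.seed)
    budget = budget or EvalBudget(cfg.budget)
    if budget.max_calls < cfg.mu:
        raise ValueError("budget must cover the initial parent population")
    span = bounds[:, 1] - bounds[:, 0]
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(dim))
    tau_prime = 1.0 / np.sqrt(2.0 * dim)

    parents = []
    for k in range(min(cfg.mu, budget.max_calls)):
        if init_parents is not None and k < len(init_parents):
            genome = np.clip(np.asarray(init_parents[k], dtype=float), bounds[:, 0], bounds[:, 1])
        else:
            genome = rng.uniform(bounds[:, 0], bounds[:, 1])
        sigma = cfg.sigma_init_frac * span.copy()
        budget.consume()
        parents.append((Individual(genome, float(objective(genome))), sigma))

    trace = []
    gen = 0
    _record(trace, gen, budget, [p for p, _ in parents])
    while budget.remaining > 0:
        gen += 1
        offspring = []
        for _ in range(min(cfg.lam, budget.remaining)):
            p, sigma = parents[rng.integers(0, len(parents))]
            global_f = np.exp(tau_prime * rng.normal())
            new_sigma = np.maximum(sigma * global_f * np.exp(tau * rng.normal(size=dim)), cfg.sigma_floor)
            genome = np.clip(p.genome + new_sigma * rng.normal(size=dim), bounds[:, 0], bounds[:, 1])
            budget.consume()
            offspring.append((Individual(genome, float(objective(genome))), new_sigma))
        merged = parents + offspring
        merged.sort(key=lambda ps: ps[0].fitness)
        parents = merged[: cfg.mu]
        _record(trace, gen, budget, [p for p, _ in parents])
    best = min((p for p, _ in parents), key=lambda ind: ind.fitness)
    return OptimizerResult(best=best, trace=trace, calls=budget.used_calls, population=[p for p, _ in parents])


@dataclasses.dataclass
class DEConfig:
    pop_size: int | None = None  # default 10*dim
    budget: int = 20_000
    seed: int = 0
    F: float = 0.5
    CR: float = 0.9


def run_de(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    cfg: DEConfig,
    budget: EvalBudget | None = None,
) -> OptimizerResult:
    """DE/rand/1/bin with greedy one-to-one replacement."""
    bounds = _check_bounds(bounds)
    dim = bounds.shape[0]
    rng = np.random.default_rng(cfg.seed)
    pop_size = cfg.pop_size or 10 * dim
    budget = budget or EvalBudget(cfg.budget)
    if budget.max_calls < pop_size:
        raise ValueError("budget must cover at least one full population")

    genomes = rng.uniform(bounds[:, 0], bounds[:, 1], size=(pop_size, dim))
    pop = []
    for g in genomes:
        budget.consume()
        pop.append(Individual(g, float(objective(g))))

    trace = []
    gen = 0
    _record(trace, gen, budget, pop)
    while budget.remaining > 0:
        gen += 1
        n_trials = min(pop_size, budget.remaining)
        for i in range(n_trials):
            idx = [j for j in range(pop_size) if j != i]
            a, b, c = (pop[j].genome for j in rng.choice(idx, size=3, replace=False))
            mutant = a + cfg.F * (b - c)
            cross = rng.random(dim) < cfg.CR
            cross[rng.integers(0, dim)] = True
            trial = np.where(cross, mutant, pop[i].genome)
            trial = np.clip(trial, bounds[:, 0], bounds[:, 1])
            budget.consume()
            f = float(objective(trial))
            if f <= pop[i].fitness:
                pop[i] = Individual(trial, f)
        _record(trace, gen, budget, pop)
    best = min(pop, key=lambda ind: ind.fitness)
    return OptimizerResult(best=best, trace=trace, calls=budget.used_calls, population=pop)


# ---------------------------------------------------------------------------
# Multi-objective machinery


def dominates(u: np.ndarray, v: np.ndarray) -> bool:
    """Crisp Pareto dominance for minimisation: u <= v everywhere, < somewhere."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return bool(np.all(u <= v) and np.any(u < v))


def pareto_rank(points: Sequence[np.ndarray]) -> np.ndarray:
    """Nondomination rank per point (0 = nondominated), by fast nondominated
    sorting."""
    pts = [np.asarray(p, dtype=float) for p in points]
    if not pts:
        return np.empty(0, dtype=int)
    m = pts[0].shape
    if any(p.shape != m for p in pts):
        raise ValueError("all objective vectors must have the same dimension")
    n = len(pts)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(pts[i], pts[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dominates(pts[j], pts[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    ranks = np.full(n, -1, dtype=int)
    front = [i for i in range(n) if n_dominating[i] == 0]
    r = 0
    while front:
        nxt = []
        for i in front:
            ranks[i] = r
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        front = nxt
        r += 1
    return ranks


def fuzzy_dominance(u: np.ndarray, v: np.ndarray, scales: np.ndarray) -> float:
    """Degree in [0, 1] to which u dominates v (minimisation).

    Per objective, the membership is the advantage (v_i - u_i) clipped to
    [0, 1] after division by a positive scale; the degree is the mean over
    objectives. Equal vectors give 0; an advantage of at least one scale in
    every objective gives 1.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    scales = np.broadcast_to(np.asarray(scales, dtype=float), u.shape)
    if np.any(scales <= 0):
        raise ValueError("fuzzy dominance scales must be positive")
    return float(np.mean(np.clip((v - u) / scales, 0.0, 1.0)))


def crowding_distance(points: Sequence[np.ndarray]) -> np.ndarray:
    """NSGA-II crowding distance within one front (boundary points infinite)."""
    pts = np.asarray([np.asarray(p, dtype=float) for p in points])
    n, m = pts.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(pts[:, k], kind="stable")
        lo, hi = pts[order[0], k], pts[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi > lo:
            dist[order[1:-1]] += (pts[order[2:], k] - pts[order[:-2], k]) / (hi - lo)
    return dist


@dataclasses.dataclass
class MOGAConfig:
    pop_size: int = 50
    budget: int = 10_000
    seed: int = 0
    crossover_prob: float = 0.9
    blx_alpha: float = 0.5
    mutation_sigma_frac: float = 0.05
    mutation_prob: float | None = None
    fuzzy: bool = False


def run_moga(
    objectives: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    cfg: MOGAConfig,
    budget: EvalBudget | None = None,
    init_population: np.ndarray | None = None,
) -> OptimizerResult:
    """Multi-objective real-coded GA (NSGA-II-style survivor selection).

    Parent selection is by binary tournament: crisp (rank, then crowding) or,
    with ``cfg.fuzzy``, by fuzzy-dominance degree with scales set to the
    current population's per-objective interquartile range. The trace records
    the best *sum of objectives* so the single- and multi-objective runs are
    comparable on the same axis; the returned ``best`` is the knee point of
    the final front (minimum sum of per-objective-normalised errors).
    """
    bounds = _check_bounds(bounds)
    dim = bounds.shape[0]
    rng = np.random.default_rng(cfg.seed)
    budget = budget or EvalBudget(cfg.budget)
    if budget.max_calls < cfg.pop_size:
        raise ValueError("budget must cover at least one full population")
    p_mut = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / dim
    span = bounds[:, 1] - bounds[:, 0]
    ga_like = GAConfig(blx_alpha=cfg.blx_alpha)

    if init_population is None:
        genomes = rng.uniform(bounds[:, 0], bounds[:, 1], size=(cfg.pop_size, dim))
    else:
        genomes = np.array(init_population, dtype=float)
    pop = []
    for g in genomes:
        budget.consume()
        pop.append(Individual(g, np.asarray(objectives(g), dtype=float)))

    trace = []
    gen = 0
    _record(trace, gen, budget, pop)
    while budget.remaining > 0:
        gen += 1
        ranks = pareto_rank([ind.fitness for ind in pop])
        crowd = _crowding_by_front(pop, ranks)
        scales = _iqr_scales(pop)
        n_children = min(cfg.pop_size, budget.remaining)
        children = []
        for _ in range(n_children):
            p1 = _mo_tournament(pop, ranks, crowd, scales, cfg, rng)
            p2 = _mo_tournament(pop, ranks, crowd, scales, cfg, rng)
            child = _blx_crossover(p1.genome, p2.genome, ga_like, rng) if rng.random() < cfg.crossover_prob else p1.genome.copy()
            mask = rng.random(dim) < p_mut
            child[mask] += rng.normal(0.0, cfg.mutation_sigma_frac * span[mask])
            child = np.clip(child, bounds[:, 0], bounds[:, 1])
            budget.consume()
            children.append(Individual(child, np.asarray(objectives(child), dtype=float)))
        pop = _nsga_survivors(pop + children, cfg.pop_size)
        _record(trace, gen, budget, pop)

    ranks = pareto_rank([ind.fitness for ind in pop])
    front = [ind for ind, r in zip(pop, ranks) if r == 0]
    best = knee_point(front)
    return OptimizerResult(best=best, trace=trace, calls=budget.used_calls, population=pop, front=front)


def knee_point(front: list[Individual]) -> Individual:
    """Minimum sum of per-objective max-normalised errors over a front."""
    objs = np.array([ind.fitness for ind in front])
    norm = objs.max(axis=0)
    norm[norm <= 0] = 1.0
    return front[int(np.argmin((objs / norm).sum(axis=1)))]


def _iqr_scales(pop: list[Individual]) -> np.ndarray:
    objs = np.array([ind.fitness for ind in pop])
    q75, q25 = np.percentile(objs, [75, 25], axis=0)
    scales = q75 - q25
    scales[scales <= 0] = 1.0
    return scales


def _crowding_by_front(pop, ranks) -> np.ndarray:
    crowd = np.zeros(len(pop))
    for r in np.unique(ranks):
        idx = np.where(ranks == r)[0]
        crowd[idx] = crowding_distance([pop[i].fitness for i in idx])
    return crowd


def _mo_tournament(pop, ranks, crowd, scales, cfg: MOGAConfig, rng) -> Individual:
    i, j = rng.integers(0, len(pop), size=2)
    if cfg.fuzzy:
        dij = fuzzy_dominance(pop[i].fitness, pop[j].fitness, scales)
        dji = fuzzy_dominance(pop[j].fitness, pop[i].fitness, scales)
        if dij > dji:
            return pop[i]
        if dji > dij:
            return pop[j]
        return pop[i] if crowd[i] >= crowd[j] else pop[j]
    if (ranks[i], -crowd[i]) <= (ranks[j], -crowd[j]):
        return pop[i]
    return pop[j]


def _nsga_survivors(merged: list[Individual], k: int) -> list[Individual]:
    ranks = pareto_rank([ind.fitness for ind in merged])
    survivors: list[Individual] = []
    for r in range(int(ranks.max()) + 1):
        idx = np.where(ranks == r)[0]
        if len(survivors) + len(idx) <= k:
            survivors.extend(merged[i] for i in idx)
        else:
            crowd = crowding_distance([merged[i].fitness for i in idx])
            order = idx[np.argsort(-crowd, kind="stable")]
            survivors.extend(merged[i] for i in order[: k - len(survivors)])
            break
        if len(survivors) == k:
            break
    return survivors
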
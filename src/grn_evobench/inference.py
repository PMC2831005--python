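"""The seven evolutionary inference algorithms.

Each algorithm maps ``(dataset, config)`` to an :class:`InferenceResult`
holding the inferred model plus run metadata (seed, fitness trace, exact
function-call count). Two organisational families exist:

Whole-network (coupled) methods
    * ``infer_clga``   — classic single-objective real-coded GA over the full
      S-System parameter vector.
    * ``infer_moga``   — the same search space with the squared-error fitness
      split into one objective per gene (crisp Pareto or fuzzy-dominance
      selection).
    * ``infer_ga_es``  — nested search: an outer binary GA over sparsity
      structures, each evaluated by a fresh inner evolution strategy fitting
      the unmasked parameters.
    * ``infer_peace1`` — iterative GA with progressive pruning of the
      smallest kinetic orders between GA cycles.

Per-gene (decoupled) methods — one gene's equation is fitted at a time, the
other genes pinned to the observed data:
    * ``infer_glsdc``  — memetic GA (genetic local search) with pattern-search
      refinement of every offspring and structure skeletalising in the local
      phase.
    * ``infer_de_aic`` — differential evolution on an AIC objective,
      N*ln(RSS/N) + 2K, with a greedy per-generation pruning pass.
    * ``infer_ga_ann`` — GA over regulator subsets for the per-gene ANN model;
      one function call = one trained network.

All methods share one cost accounting: a function call is one candidate
evaluation (one coupled or decoupled simulation of the candidate, or one
ANN training), and runs consume their budget exactly.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Callable, Sequence

import numpy as np

from .ann_model import AnnNetworkModel, dataset_scale_table, simulate_ann, train_ann
from .datasets_io import ExpressionDataset
from .ea_core import (
    DIVERGENCE_FITNESS,
    ESConfig,
    EvalBudget,
    GAConfig,
    Individual,
    MOGAConfig,
    run_es,
    run_moga,
    run_real_ga,
)
from .ssystem import (
    DecoupledGrid,
    SSystemModel,
    SolverConfig,
    simulate_decoupled,
    simulate_ssystem,
)

__all__ = [
    "InferenceConfig",
    "skeletalise",
    "InferenceResult",
    "ALGORITHMS",
    "infer",
    "infer_clga",
    "infer_moga",
    "infer_ga_es",
    "infer_ga_ann",
    "infer_peace1",
    "infer_glsdc",
    "infer_de_aic",
    "coupled_squared_error",
    "decoupled_squared_error",
    "model_data_mse",
]


@dataclasses.dataclass
class InferenceConfig:
    """Shared configuration for all inference algorithms.

    Only the fields an algorithm consumes matter to it; defaults follow the
    canonical settings of the respective method families. ``genes`` restricts
    per-gene methods to a subset (e.g. the first-five-genes protocol);
    unlisted genes keep zero parameters except for a unit degradation term.
    """

    budget: int = 10_000
    seed: int = 0
    pop_size: int = 50
    genes: Sequence[int] | None = None
    # search ranges
    rate_max: float = 20.0
    order_max: float = 3.0
    param_bounds: np.ndarray | None = None  # explicit (dim, 2) override, e.g. to pin parameters
    # integration
    solver: SolverConfig = dataclasses.field(default_factory=lambda: SolverConfig(step=0.01))
    # MOGA
    fuzzy: bool = False
    # GA+ES
    inner_es_budget: int = 500
    structure_cap: int = 5  # max nonzeros per gene per kinetic-order matrix
    lambda_c: float = 0.01  # complexity weight per nonzero kinetic order
    # GA+ANN
    fan_in: int = 4
    epochs: int = 20_000
    learning_rate: float = 0.1
    # PEACE1
    prune_fraction: float = 0.1
    n_cycles: int = 10
    # GLSDC
    tau_rel: float = 0.01
    ls_step_frac: float = 0.1
    ls_halvings: int = 3
    reseed_every: int = 10
    # DE+AIC
    de_F: float = 0.5
    de_CR: float = 0.9
    zero_tol: float = 1e-8


@dataclasses.dataclass
class InferenceResult:
    model: SSystemModel | AnnNetworkModel
    scope: str  # "whole-network" or "per-gene"
    data_mse: float
    function_calls: int
    seed: int
    trace: list[tuple[int, int, float, float]]
    wall_time: float
    algorithm: str = ""


# ---------------------------------------------------------------------------
# Fitness machinery


def _ss_bounds(n: int, cfg: InferenceConfig) -> np.ndarray:
    """Bounds for the flat [alpha, beta, g, h] encoding."""
    lo = np.concatenate([np.zeros(2 * n), -cfg.order_max * np.ones(2 * n * n)])
    hi = np.concatenate([cfg.rate_max * np.ones(2 * n), cfg.order_max * np.ones(2 * n * n)])
    return np.stack([lo, hi], axis=1)


def _gene_bounds(n: int, cfg: InferenceConfig) -> np.ndarray:
    """Bounds for one gene's [alpha_i, beta_i, g_i*, h_i*] encoding."""
    lo = np.concatenate([np.zeros(2), -cfg.order_max * np.ones(2 * n)])
    hi = np.concatenate([cfg.rate_max * np.ones(2), cfg.order_max * np.ones(2 * n)])
    return np.stack([lo, hi], axis=1)


def coupled_squared_error(
    model: SSystemModel, dataset: ExpressionDataset, solver: SolverConfig
) -> float:
    """Total squared error of the coupled simulation started from each
    series' observed initial state; divergence maps to a large penalty that
    still orders diverged candidates by how early they blew up."""
    total = 0.0
    for t, x in dataset.series:
        res = simulate_ssystem(model, np.maximum(x[0], 1e-6), t, solver)
        if res.diverged:
            return DIVERGENCE_FITNESS + 1e6 * (t.size - res.truncation_index)
        total += float(np.sum((res.trajectory - x) ** 2))
    return total


def coupled_per_gene_errors(
    model: SSystemModel, dataset: ExpressionDataset, solver: SolverConfig
) -> np.ndarray:
    """Per-gene squared-error vector of the coupled simulation (the split
    fitness used by the multi-objective methods)."""
    errs = np.zeros(model.n)
    for t, x in dataset.series:
        res = simulate_ssystem(model, np.maximum(x[0], 1e-6), t, solver)
        if res.diverged:
            return np.full(model.n, DIVERGENCE_FITNESS + 1e6 * (t.size - res.truncation_index))
        errs += np.sum((res.trajectory - x) ** 2, axis=0)
    return errs


def decoupled_squared_error(
    model: SSystemModel,
    dataset: ExpressionDataset,
    gene: int,
    solver: SolverConfig,
    grid: DecoupledGrid | None = None,
) -> float:
    """Squared error of gene ``gene``'s decoupled prediction."""
    preds = simulate_decoupled(model, dataset, gene, solver, grid=grid)
    total = 0.0
    for pred, (t, x) in zip(preds, dataset.series):
        if pred[-1] >= solver.divergence_cap:
            return DIVERGENCE_FITNESS + 1e6 * float(np.sum(pred >= solver.divergence_cap))
        total += float(np.sum((pred - x[:, gene]) ** 2))
    return total


def _gene_vector_to_model(theta: np.ndarray, gene: int, n: int) -> SSystemModel:
    """Embed one gene's [alpha, beta, g_i*, h_i*] vector in an otherwise
    inert model (only gene i's equation is ever simulated in decoupled mode)."""
    alpha = np.zeros(n)
    beta = np.zeros(n)
    g = np.zeros((n, n))
    h = np.zeros((n, n))
    alpha[gene] = theta[0]
    beta[gene] = theta[1]
    g[gene] = theta[2 : 2 + n]
    h[gene] = theta[2 + n :]
    m = object.__new__(SSystemModel)
    m.alpha, m.beta, m.g, m.h = alpha, beta, g, h
    return m


def _assemble_per_gene(
    gene_vectors: dict[int, np.ndarray], n: int
) -> SSystemModel:
    alpha = np.zeros(n)
    beta = np.ones(n)  # unit decay placeholder for genes outside the protocol
    g = np.zeros((n, n))
    h = np.zeros((n, n))
    for i in range(n):
        h[i, i] = 1.0
    for i, theta in gene_vectors.items():
        alpha[i] = theta[0]
        beta[i] = theta[1]
        g[i] = theta[2 : 2 + n]
        h[i] = theta[2 + n :]
    return SSystemModel(alpha=alpha, beta=beta, g=g, h=h)


def model_data_mse(model, dataset: ExpressionDataset, solver: SolverConfig | None = None) -> float:
    """Data MSE of a model's own free-running simulation against the dataset
    (mean over genes, time points and series) — the goodness-of-fit criterion."""
    solver = solver or SolverConfig()
    sq, count = 0.0, 0
    if isinstance(model, SSystemModel):
        for t, x in dataset.series:
            res = simulate_ssystem(model, np.maximum(x[0], 1e-6), t, solver)
            sq += float(np.sum((res.trajectory - x) ** 2))
            count += x.size
    else:
        for t, x in dataset.series:
            traj = simulate_ann(model, x[0], t.size - 1) if t.size > 1 else x[:1].copy()
            sq += float(np.sum((traj - x) ** 2))
            count += x.size
    return sq / count


def _split_budget(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if k < rem else 0) for k in range(parts)]


def _gene_list(dataset: ExpressionDataset, cfg: InferenceConfig) -> list[int]:
    return list(cfg.genes) if cfg.genes is not None else list(range(dataset.n_genes))


def _result(model, scope, dataset, cfg, budget, trace, t0, name) -> InferenceResult:
    return InferenceResult(
        model=model,
        scope=scope,
        data_mse=model_data_mse(model, dataset, cfg.solver),
        function_calls=budget.used_calls,
        seed=cfg.seed,
        trace=trace,
        wall_time=time.perf_counter() - t0,
        algorithm=name,
    )


# ---------------------------------------------------------------------------
# Whole-network methods


def infer_clga(dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Classic single-objective GA over the full S-System parameter vector;
    fitness is the coupled-simulation squared error summed over genes, time
    points and series."""
    t0 = time.perf_counter()
    n = dataset.n_genes
    budget = EvalBudget(cfg.budget)

    def objective(theta: np.ndarray) -> float:
        return coupled_squared_error(SSystemModel._from_vector_unchecked(theta, n), dataset, cfg.solver)

    bounds = cfg.param_bounds if cfg.param_bounds is not None else _ss_bounds(n, cfg)
    res = run_real_ga(objective, bounds, GAConfig(pop_size=cfg.pop_size, seed=cfg.seed), budget=budget)
    model = SSystemModel.from_parameter_vector(res.best.genome, n)
    return _result(model, "whole-network", dataset, cfg, budget, res.trace, t0, "clga")


def infer_moga(dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Multi-objective GA: the coupled squared error split into one objective
    per gene; survivor selection by nondominated sorting, parent tournaments
    crisp or fuzzy (``cfg.fuzzy``); the returned model is the knee point of
    the final front."""
    t0 = time.perf_counter()
    n = dataset.n_genes
    budget = EvalBudget(cfg.budget)

    def objectives(theta: np.ndarray) -> np.ndarray:
        return coupled_per_gene_errors(SSystemModel._from_vector_unchecked(theta, n), dataset, cfg.solver)

    res = run_moga(
        objectives,
        _ss_bounds(n, cfg),
        MOGAConfig(pop_size=cfg.pop_size, seed=cfg.seed, fuzzy=cfg.fuzzy),
        budget=budget,
    )
    model = SSystemModel.from_parameter_vector(res.best.genome, n)
    name = "fmoga" if cfg.fuzzy else "moga"
    return _result(model, "whole-network", dataset, cfg, budget, res.trace, t0, name)


def _mask_bounds_ga_es(n: int) -> int:
    return 2 * n * n  # one structure bit per kinetic order


def infer_ga_es(dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Nested structure/parameter search: an outer binary GA proposes which
    kinetic orders are nonzero (at most ``cfg.structure_cap`` per gene per
    matrix); each structure is scored by running a fresh inner (mu+lambda) ES
    over the masked parameter vector. Structure fitness is the inner best
    error plus ``cfg.lambda_c`` per nonzero; all inner ES calls are charged
    against the global budget."""
    t0 = time.perf_counter()
    n = dataset.n_genes
    nbits = _mask_bounds_ga_es(n)
    rng = np.random.default_rng(cfg.seed)
    budget = EvalBudget(cfg.budget)
    bounds = _ss_bounds(n, cfg)
    trace: list[tuple[int, int, float, float]] = []

    def repair(mask: np.ndarray) -> np.ndarray:
        mask = mask.copy()
        for mat in (0, 1):
            rows = mask[mat * n * n : (mat + 1) * n * n].reshape(n, n)
            for i in range(n):
                extra = int(rows[i].sum()) - cfg.structure_cap
                if extra > 0:
                    on = np.nonzero(rows[i])[0]
                    rows[i, rng.choice(on, size=extra, replace=False)] = 0
        return mask

    def fit_structure(mask: np.ndarray, inner_calls: int, inner_seed: int, warm: np.ndarray | None):
        """Run the inner ES on the masked parameters; returns (error, theta).

        One initial parent is inherited from the best parameter vector found
        so far (Lamarckian warm start); the rest are random, so new
        structures still get an unbiased fit of their own.
        """
        full_mask = np.concatenate([np.ones(2 * n), mask]).astype(bool)

        def objective(theta: np.ndarray) -> float:
            masked = np.where(full_mask, theta, 0.0)
            return coupled_squared_error(SSystemModel._from_vector_unchecked(masked, n), dataset, cfg.solver)

        inner_budget = EvalBudget(inner_calls)
        # small, greedy inner ES: structure evaluations are many and cheap
        es_cfg = ESConfig(mu=3, lam=12, seed=inner_seed, sigma_init_frac=0.05)
        res = run_es(objective, bounds, es_cfg, budget=inner_budget, init_parents=None if warm is None else warm[None, :])
        budget.consume(inner_budget.used_calls)
        theta = np.where(full_mask, res.best.genome, 0.0)
        return res.best.fitness, theta

    pop_n = max(4, cfg.pop_size // 5)
    masks = [repair((rng.random(nbits) < 0.3).astype(int)) for _ in range(pop_n)]
    pop: list[tuple[float, np.ndarray, float, np.ndarray]] = []  # (struct_fit, mask, err, theta)
    gen = 0
    for mask in masks:
        if budget.remaining <= 0:
            break
        warm = min(pop, key=lambda s: s[2])[3] if pop else None
        err, theta = fit_structure(mask, min(cfg.inner_es_budget, budget.remaining), int(rng.integers(2**31)), warm)
        pop.append((err + cfg.lambda_c * mask.sum(), mask, err, theta))
    best = min(pop, key=lambda s: s[0])
    trace.append((gen, budget.used_calls, best[0], float(np.median([s[0] for s in pop]))))

    while budget.remaining > 0:
        gen += 1
        children = []
        while budget.remaining > 0 and len(children) < pop_n - 1:
            i, j = rng.integers(0, len(pop), size=2)
            p1 = pop[min(i, j, key=lambda k: pop[k][0])][1]
            k, l = rng.integers(0, len(pop), size=2)
            p2 = pop[min(k, l, key=lambda m: pop[m][0])][1]
            cross = rng.random(nbits) < 0.5
            child = np.where(cross, p1, p2)
            flip = rng.random(nbits) < (1.0 / nbits)
            child = repair(np.where(flip, 1 - child, child))
            err, theta = fit_structure(child, min(cfg.inner_es_budget, budget.remaining), int(rng.integers(2**31)), best[3])
            children.append((err + cfg.lambda_c * child.sum(), child, err, theta))
        pop = sorted(pop + children, key=lambda s: s[0])[:pop_n]
        best = min(best, pop[0], key=lambda s: s[0])
        trace.append((gen, budget.used_calls, best[0], float(np.median([s[0] for s in pop]))))

    model = SSystemModel.from_parameter_vector(best[3], n)
    return _result(model, "whole-network", dataset, cfg, budget, trace, t0, "gaes")


def infer_peace1(dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Iterative GA with progressive pruning: after each GA cycle the
    fraction ``cfg.prune_fraction`` of the smallest-magnitude still-free
    kinetic orders of the cycle's best model is fixed at zero; the next cycle
    restarts from perturbed copies of the pruned best. Zeroed entries never
    return; cycles continue until the budget is exhausted."""
    t0 = time.perf_counter()
    n = dataset.n_genes
    rng = np.random.default_rng(cfg.seed)
    budget = EvalBudget(cfg.budget)
    bounds = _ss_bounds(n, cfg)
    dim = bounds.shape[0]
    span = bounds[:, 1] - bounds[:, 0]
    order_mask = np.ones(2 * n * n, dtype=bool)  # kinetic orders still free
    trace: list[tuple[int, int, float, float]] = []
    best_theta = None
    best_fit = np.inf
    cycle_budgets = _split_budget(cfg.budget, cfg.n_cycles)

    for cycle, cyc_budget in enumerate(cycle_budgets):
        if cyc_budget < cfg.pop_size:
            cyc_budget = min(budget.remaining, cfg.pop_size)
        cyc_budget = min(cyc_budget, budget.remaining)
        if cyc_budget <= 0:
            break
        full_mask = np.concatenate([np.ones(2 * n, dtype=bool), order_mask])

        def objective(theta: np.ndarray) -> float:
            masked = np.where(full_mask, theta, 0.0)
            return coupled_squared_error(SSystemModel._from_vector_unchecked(masked, n), dataset, cfg.solver)

        init = None
        if best_theta is not None:
            init = np.tile(best_theta, (cfg.pop_size, 1))
            init[1:] += rng.normal(0.0, 0.05 * span, size=(cfg.pop_size - 1, dim))
            init = np.clip(init, bounds[:, 0], bounds[:, 1])
        cyc = EvalBudget(cyc_budget)
        res = run_real_ga(
            objective,
            bounds,
            GAConfig(pop_size=min(cfg.pop_size, cyc_budget), seed=int(rng.integers(2**31))),
            budget=cyc,
            init_population=init[: min(cfg.pop_size, cyc_budget)] if init is not None else None,
        )
        budget.consume(cyc.used_calls)
        offset = len(trace)
        for g_, c_, b_, m_ in res.trace:
            trace.append((offset + g_, budget.used_calls - cyc.used_calls + c_, min(b_, best_fit), m_))
        cand = np.where(full_mask, res.best.genome, 0.0)
        if res.best.fitness < best_fit:
            best_fit = res.best.fitness
            best_theta = cand
        # prune: zero the smallest-|order| fraction of the still-free entries
        # (skipped once the budget is spent — the returned model is always a
        # model the search actually fitted)
        orders = np.abs(best_theta[2 * n :])
        free = np.nonzero(order_mask)[0]
        k = int(np.floor(cfg.prune_fraction * free.size))
        if k > 0 and budget.remaining > 0:
            drop = free[np.argsort(orders[free], kind="stable")[:k]]
            order_mask[drop] = False
            best_theta = best_theta.copy()
            best_theta[2 * n :][~order_mask] = 0.0
            # pruning invalidates the stored fitness; the next cycle re-scores
            # the pruned seed as part of its initial population
            best_fit = np.inf

    model = SSystemModel.from_parameter_vector(best_theta, n)
    return _result(model, "whole-network", dataset, cfg, budget, trace, t0, "peace1")


# ---------------------------------------------------------------------------
# Per-gene (decoupled) methods


def skeletalise(
    theta: np.ndarray,
    f: float,
    evaluate: Callable[[np.ndarray], float],
    tau_rel: float,
    first_dim: int = 2,
    remaining: Callable[[], int] | None = None,
) -> tuple[np.ndarray, float]:
    """Structure skeletalising: zero every kinetic order whose removal
    changes the objective by less than ``tau_rel`` relatively.

    This is the sparsity/noise-control device of the genetic-local-search
    method: parameters that only chase noise barely move the objective, so
    they are pinned to exactly zero. ``theta`` is a per-gene parameter
    vector [alpha, beta, g_i*, h_i*]; entries before ``first_dim`` (the rate
    constants) are never zeroed.
    """
    theta = theta.copy()
    for d in range(first_dim, theta.size):
        if theta[d] == 0.0 or (remaining is not None and remaining() <= 0):
            continue
        probe = theta.copy()
        probe[d] = 0.0
        fp = evaluate(probe)
        if fp - f <= tau_rel * max(abs(f), 1e-12):
            theta, f = probe, fp
    return theta, f


def infer_glsdc(dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Genetic local search with decoupled fitness: per gene, a GA whose
    every offspring is refined by coordinate pattern search. The local phase
    skeletalises the structure — a kinetic order whose zeroing changes the
    objective by less than ``cfg.tau_rel`` (relatively) is fixed at zero,
    which both sparsifies the model and suppresses noise-fitted terms. The
    worst half of the population is re-randomised every ``cfg.reseed_every``
    generations."""
    t0 = time.perf_counter()
    n = dataset.n_genes
    genes = _gene_list(dataset, cfg)
    budget = EvalBudget(cfg.budget)
    grid = DecoupledGrid(dataset, step=cfg.solver.step)
    bounds = _gene_bounds(n, cfg)
    dim = bounds.shape[0]
    span = bounds[:, 1] - bounds[:, 0]
    rng = np.random.default_rng(cfg.seed)
    gene_vectors: dict[int, np.ndarray] = {}
    trace: list[tuple[int, int, float, float]] = []
    pop_n = max(4, cfg.pop_size // 5)

    for gene, gene_budget in zip(genes, _split_budget(cfg.budget, len(genes))):
        sub = EvalBudget(min(gene_budget, budget.remaining))

        def objective(theta: np.ndarray) -> float:
            return decoupled_squared_error(_gene_vector_to_model(theta, gene, n), dataset, gene, cfg.solver, grid)

        def evaluate(theta: np.ndarray) -> float:
            sub.consume()
            return objective(theta)

        def local_search(theta: np.ndarray, f: float) -> tuple[np.ndarray, float]:
            theta = theta.copy()
            step = cfg.ls_step_frac * span
            for _ in range(cfg.ls_halvings + 1):
                for d in range(dim):
                    if sub.remaining <= 0:
                        return theta, f
                    for direction in (+1.0, -1.0):
                        probe = theta.copy()
                        probe[d] = np.clip(probe[d] + direction * step[d], bounds[d, 0], bounds[d, 1])
                        fp = evaluate(probe)
                        if fp < f:
                            theta, f = probe, fp
                            break
                        if sub.remaining <= 0:
                            return theta, f
                step = step / 2.0
            return skeletalise(theta, f, evaluate, cfg.tau_rel, remaining=lambda: sub.remaining)

        pop = []
        for _ in range(min(pop_n, sub.remaining)):
            g0 = rng.uniform(bounds[:, 0], bounds[:, 1])
            pop.append((g0, evaluate(g0)))
        gen = 0
        trace.append((gen, budget.used_calls + sub.used_calls,
                      min(p[1] for p in pop), float(np.median([p[1] for p in pop]))))
        while sub.remaining > 0:
            gen += 1
            if cfg.reseed_every and gen % cfg.reseed_every == 0 and sub.remaining > len(pop) // 2:
                pop.sort(key=lambda p: p[1])
                keep = pop[: max(1, len(pop) // 2)]
                fresh = []
                for _ in range(len(pop) - len(keep)):
                    if sub.remaining <= 0:
                        break
                    g0 = rng.uniform(bounds[:, 0], bounds[:, 1])
                    fresh.append((g0, evaluate(g0)))
                pop = keep + fresh
            children = []
            while sub.remaining > 0 and len(children) < max(1, pop_n // 2):
                i, j = rng.integers(0, len(pop), size=2)
                p1 = pop[i] if pop[i][1] <= pop[j][1] else pop[j]
                k, l = rng.integers(0, len(pop), size=2)
                p2 = pop[k] if pop[k][1] <= pop[l][1] else pop[l]
                lo = np.minimum(p1[0], p2[0])
                hi = np.maximum(p1[0], p2[0])
                d = 0.5 * (hi - lo)
                child = rng.uniform(lo - d, hi + d)
                mask = rng.random(dim) < 1.0 / dim
                child[mask] += rng.normal(0.0, 0.05 * span[mask])
                child = np.clip(child, bounds[:, 0], bounds[:, 1])
                f = evaluate(child)
                child, f = local_search(child, f)
                children.append((child, f))
            pop = sorted(pop + children, key=lambda p: p[1])[:pop_n]
            trace.append((gen, budget.used_calls + sub.used_calls, pop[0][1], float(np.median([p[1] for p in pop]))))
        budget.consume(sub.used_calls)
        gene_vectors[gene] = min(pop, key=lambda p: p[1])[0]

    model = _assemble_per_gene(gene_vectors, n)
    return _result(model, "per-gene", dataset, cfg, budget, trace, t0, "glsdc")


def aic_fitness(rss: float, n_points: int, n_params: int) -> float:
    """Akaike objective N*ln(RSS/N) + 2K (RSS floored to keep the log finite)."""
    return n_points * float(np.log(max(rss, 1e-300) / n_points)) + 2 * n_params


def infer_de_aic(dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Per-gene differential evolution on the AIC objective: the residual
    sum of squares of the gene's decoupled prediction plus a 2-per-parameter
    sparsity penalty (a parameter counts when its magnitude exceeds
    ``cfg.zero_tol``). After each generation the incumbent best is subjected
    to a greedy pruning pass that zeroes any kinetic order whose removal
    decreases the objective."""
    t0 = time.perf_counter()
    n = dataset.n_genes
    genes = _gene_list(dataset, cfg)
    budget = EvalBudget(cfg.budget)
    grid = DecoupledGrid(dataset, step=cfg.solver.step)
    bounds = _gene_bounds(n, cfg)
    dim = bounds.shape[0]
    rng = np.random.default_rng(cfg.seed)
    gene_vectors: dict[int, np.ndarray] = {}
    trace: list[tuple[int, int, float, float]] = []
    n_points_total = dataset.n_points

    for gene, gene_budget in zip(genes, _split_budget(cfg.budget, len(genes))):
        sub = EvalBudget(min(gene_budget, budget.remaining))

        def objective(theta: np.ndarray) -> float:
            rss = decoupled_squared_error(_gene_vector_to_model(theta, gene, n), dataset, gene, cfg.solver, grid)
            if rss >= DIVERGENCE_FITNESS:
                return rss
            k_params = int(np.sum(np.abs(theta) > cfg.zero_tol))
            return aic_fitness(rss, n_points_total, k_params)

        pop_size = min(10 * dim, max(4, sub.max_calls // 4))
        pop_g = rng.uniform(bounds[:, 0], bounds[:, 1], size=(pop_size, dim))
        pop = []
        for g0 in pop_g:
            if sub.remaining <= 0:
                break
            sub.consume()
            pop.append(Individual(g0, float(objective(g0))))
        gen = 0
        best = min(pop, key=lambda ind: ind.fitness)
        trace.append((gen, budget.used_calls + sub.used_calls, best.fitness, float(np.median([p.fitness for p in pop]))))
        while sub.remaining > 0:
            gen += 1
            for i in range(min(len(pop), sub.remaining)):
                idx = [j for j in range(len(pop)) if j != i]
                a, b, c = (pop[j].genome for j in rng.choice(idx, size=3, replace=False))
                mutant = a + cfg.de_F * (b - c)
                cross = rng.random(dim) < cfg.de_CR
                cross[rng.integers(0, dim)] = True
                child = np.clip(np.where(cross, mutant, pop[i].genome), bounds[:, 0], bounds[:, 1])
                sub.consume()
                f = float(objective(child))
                if f <= pop[i].fitness:
                    pop[i] = Individual(child, f)
            # greedy pruning pass on the incumbent best
            b_idx = int(np.argmin([p.fitness for p in pop]))
            theta = pop[b_idx].genome.copy()
            f_best = pop[b_idx].fitness
            order_idx = np.argsort(np.abs(theta[2:]), kind="stable") + 2
            for d in order_idx:
                if sub.remaining <= 0:
                    break
                if theta[d] == 0.0:
                    continue
                probe = theta.copy()
                probe[d] = 0.0
                sub.consume()
                fp = float(objective(probe))
                if fp < f_best:
                    theta, f_best = probe, fp
            if f_best < pop[b_idx].fitness:
                pop[b_idx] = Individual(theta, f_best)
            best = min(pop, key=lambda ind: ind.fitness)
            trace.append((gen, budget.used_calls + sub.used_calls, best.fitness, float(np.median([p.fitness for p in pop]))))
        budget.consume(sub.used_calls)
        theta = min(pop, key=lambda ind: ind.fitness).genome.copy()
        theta[np.abs(theta) <= cfg.zero_tol] = 0.0
        gene_vectors[gene] = theta

    model = _assemble_per_gene(gene_vectors, n)
    return _result(model, "per-gene", dataset, cfg, budget, trace, t0, "deaic")


def infer_ga_ann(dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Per-gene GA over regulator subsets for the one-step-ahead ANN model.

    One outer evaluation = one ANN trained by gradient descent = one function
    call. The assembled network keeps, per gene, the subset whose trained
    scaled-space MSE was lowest."""
    t0 = time.perf_counter()
    n = dataset.n_genes
    genes = _gene_list(dataset, cfg)
    budget = EvalBudget(cfg.budget)
    rng = np.random.default_rng(cfg.seed)
    table = dataset_scale_table(dataset)
    best_models: dict[int, tuple] = {}
    trace: list[tuple[int, int, float, float]] = []
    k = min(cfg.fan_in, n)
    pop_n = max(4, min(12, cfg.pop_size // 4))

    def repair(mask: np.ndarray) -> np.ndarray:
        on = np.nonzero(mask)[0]
        if on.size > k:
            mask = mask.copy()
            mask[rng.choice(on, size=on.size - k, replace=False)] = 0
        return mask

    for gene, gene_budget in zip(genes, _split_budget(cfg.budget, len(genes))):
        sub = EvalBudget(min(gene_budget, budget.remaining))

        def evaluate(mask: np.ndarray):
            sub.consume()
            regs = tuple(int(j) for j in np.nonzero(mask)[0])
            model, mse = train_ann(
                regs, gene, dataset,
                epochs=cfg.epochs, learning_rate=cfg.learning_rate,
                seed=int(rng.integers(2**31)), fan_in_limit=k, scale_table=table,
            )
            return model, mse

        pop = []
        for _ in range(min(pop_n, sub.remaining)):
            mask = repair((rng.random(n) < min(0.5, k / n)).astype(int))
            model, mse = evaluate(mask)
            pop.append((mse, mask, model))
        gen = 0
        trace.append((gen, budget.used_calls + sub.used_calls,
                      min(p[0] for p in pop), float(np.median([p[0] for p in pop]))))
        while sub.remaining > 0:
            gen += 1
            children = []
            while sub.remaining > 0 and len(children) < pop_n:
                i, j = rng.integers(0, len(pop), size=2)
                p1 = pop[i] if pop[i][0] <= pop[j][0] else pop[j]
                i, j = rng.integers(0, len(pop), size=2)
                p2 = pop[i] if pop[i][0] <= pop[j][0] else pop[j]
                cross = rng.random(n) < 0.5
                child = np.where(cross, p1[1], p2[1])
                flip = rng.random(n) < 1.0 / n
                child = repair(np.where(flip, 1 - child, child).astype(int))
                model, mse = evaluate(child)
                children.append((mse, child, model))
            pop = sorted(pop + children, key=lambda p: p[0])[:pop_n]
            trace.append((gen, budget.used_calls + sub.used_calls, pop[0][0], float(np.median([p[0] for p in pop]))))
        budget.consume(sub.used_calls)
        best_models[gene] = min(pop, key=lambda p: p[0])

    gene_list = []
    for i in range(n):
        if i in best_models:
            gene_list.append(best_models[i][2])
        else:
            from .ann_model import AnnGeneModel

            gene_list.append(
                AnnGeneModel(
                    gene_index=i, regulators=(), weights=np.empty(0), bias=0.0,
                    scale_min=float(table[i, 0]), scale_max=float(table[i, 1]),
                )
            )
    network = AnnNetworkModel(genes=gene_list, gene_names=list(dataset.gene_names))
    return _result(network, "per-gene", dataset, cfg, budget, trace, t0, "gaann")


ALGORITHMS: dict[str, Callable[[ExpressionDataset, InferenceConfig], InferenceResult]] = {
    "clga": infer_clga,
    "moga": lambda d, c: infer_moga(d, dataclasses.replace(c, fuzzy=False)),
    "fmoga": lambda d, c: infer_moga(d, dataclasses.replace(c, fuzzy=True)),
    "gaes": infer_ga_es,
    "gaann": infer_ga_ann,
    "peace1": infer_peace1,
    "glsdc": infer_glsdc,
    "deaic": infer_de_aic,
}


def infer(algorithm: str, dataset: ExpressionDataset, cfg: InferenceConfig) -> InferenceResult:
    """Dispatch by algorithm name (see :data:`ALGORITHMS`)."""
    try:
        fn = ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}") from None
    return fn(dataset, cfg)
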
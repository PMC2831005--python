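"""Synthetic benchmark generation: scale-free sparse regulatory networks,
simulated expression time series, and Gaussian noise injection.

Real regulatory networks are sparse and their connectivity is heavy-tailed
(a few hub regulators, many weakly connected genes). The generator samples a
directed network by preferential attachment — each gene draws its regulators
with probability proportional to the candidates' current out-degree — with
per-gene in-degree confined to a small range (3-5 regulators by default,
capped at n-1 for very small networks). Nonzero kinetic orders (S-System) or
weights (ANN) are drawn for existing edges only; every gene always carries a
degradation self-term.

Datasets emulate sparse time-course designs: a handful of short series from
randomised initial conditions, totalling 60 points for networks of up to 20
genes, 80 at 30 genes and 125 at 50 genes. Measurement noise is multiplicative
Gaussian: each value x becomes x*(1+eps) with eps ~ N(0, level), at levels of
1, 2, 5 or 10%.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .ann_model import AnnGeneModel, AnnNetworkModel, simulate_ann
from .datasets_io import ExpressionDataset
from .ssystem import STATE_FLOOR, SSystemModel, SolverConfig, simulate_ssystem

__all__ = [
    "BenchmarkSpec",
    "generate_network",
    "generate_dataset",
    "add_noise",
    "generate_benchmark",
    "default_n_time_points",
    "truth_edges",
]


def default_n_time_points(n_genes: int) -> int:
    """Benchmark time-point budget by network size (60 / 80 / 125)."""
    if n_genes <= 20:
        return 60
    if n_genes <= 30:
        return 80
    return 125


@dataclasses.dataclass
class BenchmarkSpec:
    """Conditions for one synthetic benchmark dataset.

    Defaults follow the study design: connectivity 3-5 regulators per gene
    (capped at n-1), a time-point total of 60/80/125 by size, and noise-free
    data (noise is added separately so criteria can be tracked against the
    noiseless truth).
    """

    n_genes: int
    model_type: Literal["ssystem", "ann"] = "ssystem"
    connectivity: tuple[int, int] | None = None  # (min, max) regulators/gene
    n_time_points: int | None = None
    n_series: int | None = None
    noise_level: float = 0.0
    seed: int = 0
    sample_dt: float = 0.05  # spacing of S-System sample times
    solver: SolverConfig = dataclasses.field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.connectivity is None:
            self.connectivity = (min(3, self.n_genes - 1), min(5, self.n_genes - 1))
        cmin, cmax = self.connectivity
        if not (1 <= cmin <= cmax):
            raise ValueError(f"bad connectivity range {self.connectivity}")
        if cmax >= self.n_genes:
            raise ValueError(
                f"connectivity max {cmax} must be < n_genes {self.n_genes}"
            )
        if self.n_time_points is None:
            self.n_time_points = default_n_time_points(self.n_genes)
        if self.n_series is None:
            # 4 short series for the 60/80-point designs, 5 for the 125-point one
            self.n_series = 5 if self.n_time_points >= 100 else 4
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    def series_lengths(self) -> list[int]:
        """Partition the time-point total into near-equal series."""
        base = self.n_time_points // self.n_series
        rem = self.n_time_points % self.n_series
        return [base + (1 if k < rem else 0) for k in range(self.n_series)]


def _sample_regulators(spec: BenchmarkSpec, rng: np.random.Generator) -> list[list[int]]:
    """Preferential-attachment regulator sets: gene j is chosen as a regulator
    with probability proportional to 1 + its current out-degree."""
    n = spec.n_genes
    cmin, cmax = spec.connectivity
    out_degree = np.zeros(n)
    regulators: list[list[int]] = [[] for _ in range(n)]
    for i in rng.permutation(n):
        d = int(rng.integers(cmin, cmax + 1))
        candidates = np.array([j for j in range(n) if j != i])
        w = 1.0 + out_degree[candidates]
        chosen = rng.choice(candidates, size=d, replace=False, p=w / w.sum())
        regulators[i] = sorted(int(j) for j in chosen)
        out_degree[chosen] += 1
    return regulators


def _kinetic_order(rng: np.random.Generator, lo: float = 0.1, hi: float = 3.0) -> float:
    """Magnitude uniform in [lo, hi], random sign."""
    return float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))


def generate_network(spec: BenchmarkSpec, rng: np.random.Generator | None = None):
    """Sample a ground-truth model for ``spec``; deterministic per spec.seed.

    Returns ``(model, edges)`` where ``edges`` is the truth edge set as a
    sorted list of ``(regulator, target, sign)`` triples (self-degradation
    loops included).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.model_type == "ssystem":
        return _generate_ssystem(spec, rng)
    if spec.model_type == "ann":
        return _generate_ann(spec, rng)
    raise ValueError(f"unknown model_type {spec.model_type!r}")


def _generate_ssystem(spec: BenchmarkSpec, rng: np.random.Generator):
    n = spec.n_genes
    regulators = _sample_regulators(spec, rng)
    alpha = rng.uniform(2.0, 15.0, size=n)
    beta = rng.uniform(2.0, 15.0, size=n)
    g = np.zeros((n, n))
    h = np.zeros((n, n))
    for i in range(n):
        # degradation self-term always present (first-order-like decay)
        h[i, i] = rng.uniform(0.5, 2.0)
        for j in regulators[i]:
            # each regulator acts through synthesis or degradation kinetics
            if rng.random() < 0.5:
                g[i, j] = _kinetic_order(rng, hi=2.0)
            else:
                h[i, j] = _kinetic_order(rng, hi=2.0)
    model = SSystemModel(alpha=alpha, beta=beta, g=g, h=h)
    return model, truth_edges(model)


def _generate_ann(spec: BenchmarkSpec, rng: np.random.Generator):
    n = spec.n_genes
    regulators = _sample_regulators(spec, rng)
    lo = rng.uniform(0.0, 0.5, size=n)
    hi = rng.uniform(1.5, 3.0, size=n)
    genes = []
    for i in range(n):
        regs = tuple(regulators[i])
        w = np.array([rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 6.0) for _ in regs])
        genes.append(
            AnnGeneModel(
                gene_index=i,
                regulators=regs,
                weights=w,
                bias=float(rng.uniform(-1.0, 1.0)),
                scale_min=float(lo[i]),
                scale_max=float(hi[i]),
            )
        )
    model = AnnNetworkModel(genes=genes, gene_names=[f"G{i+1}" for i in range(n)])
    return model, truth_edges(model)


def truth_edges(model, zero_tol: float = 0.0) -> list[tuple[int, int, int]]:
    """Signed edge list of a ground-truth model (see evaluation module for
    the unsigned extraction used in scoring). Sign convention: positive if the
    regulator increases synthesis (g > 0) or decreases degradation (h < 0)."""
    edges = []
    if isinstance(model, SSystemModel):
        for i in range(model.n):
            for j in range(model.n):
                gij, hij = model.g[i, j], model.h[i, j]
                if abs(gij) > zero_tol or abs(hij) > zero_tol:
                    sign = 1 if (abs(gij) > zero_tol and gij > 0) or (abs(gij) <= zero_tol and hij < 0) else -1
                    edges.append((j, i, sign))
    else:
        for gm in model.genes:
            for r, w in zip(gm.regulators, gm.weights):
                if abs(w) > zero_tol:
                    edges.append((r, gm.gene_index, 1 if w > 0 else -1))
    return sorted(edges)


def generate_dataset(
    model,
    spec: BenchmarkSpec,
    rng: np.random.Generator | None = None,
    max_retries: int = 25,
) -> ExpressionDataset:
    """Simulate noiseless time series from ``model`` under ``spec``.

    Initial states are drawn uniformly from [0.5, 2] (within each gene's
    scaling range for ANN models); a series whose integration diverges is
    re-drawn from a fresh initial state, up to ``max_retries`` attempts.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    names = [f"G{i+1}" for i in range(spec.n_genes)]
    series = []
    for m in spec.series_lengths():
        ok = False
        for _ in range(max_retries):
            if isinstance(model, SSystemModel):
                t = np.arange(m) * spec.sample_dt
                x0 = rng.uniform(0.5, 2.0, size=spec.n_genes)
                res = simulate_ssystem(model, x0, t, spec.solver)
                if res.diverged:
                    continue
                series.append((t, res.trajectory))
            else:
                table = model.scale_table()
                x0 = rng.uniform(table[:, 0], table[:, 1])
                traj = simulate_ann(model, x0, m - 1)
                series.append((np.arange(m, dtype=float), traj))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"dataset generation failed: {max_retries} divergent initial states"
            )
    return ExpressionDataset(series=series, gene_names=names)


def add_noise(
    dataset: ExpressionDataset,
    level: float,
    seed: int = 0,
    mode: Literal["relative", "absolute"] = "relative",
) -> ExpressionDataset:
    """Inject Gaussian measurement noise at the given level.

    ``relative`` (default): x -> x*(1+eps), eps ~ N(0, level), i.e. ``level``
    is the noise standard deviation as a fraction of the signal. ``absolute``:
    x -> x + eps with eps ~ N(0, level) in expression units. Values are
    floored at the simulation state floor; deterministic per seed.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return ExpressionDataset(
            series=[(t.copy(), x.copy()) for t, x in dataset.series],
            gene_names=list(dataset.gene_names),
        )
    rng = np.random.default_rng(seed)
    noisy = []
    for t, x in dataset.series:
        eps = rng.normal(0.0, level, size=x.shape)
        xn = x * (1.0 + eps) if mode == "relative" else x + eps
        noisy.append((t.copy(), np.maximum(xn, STATE_FLOOR)))
    return ExpressionDataset(series=noisy, gene_names=list(dataset.gene_names))


def generate_benchmark(spec: BenchmarkSpec, max_network_retries: int = 10):
    """Full pipeline: network + noiseless data (+ noise if spec asks for it).

    Returns ``(model, edges, dataset)``. A truth network for which no
    non-divergent dataset can be simulated is discarded and re-sampled, so the
    pipeline is still deterministic per spec.seed.
    """
    for attempt in range(max_network_retries):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        model, edges = generate_network(spec, rng)
        try:
            dataset = generate_dataset(model, spec, rng)
        except RuntimeError:
            continue
        if spec.noise_level > 0:
            dataset = add_noise(dataset, spec.noise_level, seed=spec.seed + 7919)
        return model, edges, dataset
    raise RuntimeError("could not generate a stable benchmark network")
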
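"""Per-gene artificial-neural-network regulatory model.

Each gene is modelled by a single sigmoid unit that predicts the gene's
expression at the next sampled time point from the expression of a small set
of regulator genes at the current point (one-step-ahead prediction, not a
derivative model). With a fan-in limit of k regulators plus a bias this costs
k+1 parameters per gene — n*(k+1) for the network, e.g. 25 for a 5-gene
network at k=4, versus the 60 of the corresponding 5-gene S-System.

Expression is mapped per gene from its observed [min, max] range onto
[0.1, 0.9] before entering the sigmoid, and mapped back afterwards; the
margin keeps training targets away from the saturated tails.

Training is full-batch gradient descent (delta rule) on the squared one-step
prediction error in scaled space, pooled over all series of a dataset.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .datasets_io import ExpressionDataset

__all__ = [
    "AnnGeneModel",
    "AnnNetworkModel",
    "ann_predict_next",
    "train_ann",
    "simulate_ann",
    "SCALED_LO",
    "SCALED_HI",
]

SCALED_LO = 0.1
SCALED_HI = 0.9


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclasses.dataclass
class AnnGeneModel:
    """Single-unit predictor for one gene.

    ``regulators`` is the ordered tuple of regulator gene indices (at most the
    fan-in limit, enforced by the training/search layer), ``weights`` aligns
    with it, and ``scale_min``/``scale_max`` record the per-gene expression
    range used by the [0.1, 0.9] scaling. The same scaling (of each regulator
    gene's own range) is applied to the inputs, so a network's gene models
    must share one consistent per-gene range table.
    """

    gene_index: int
    regulators: tuple[int, ...]
    weights: np.ndarray
    bias: float
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        self.regulators = tuple(int(r) for r in self.regulators)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.regulators)) != len(self.regulators):
            raise ValueError("duplicate regulators")
        if self.weights.shape != (len(self.regulators),):
            raise ValueError("one weight per regulator required")
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValueError("non-finite parameters")
        if not self.scale_min < self.scale_max:
            raise ValueError("scaling requires min < max")


@dataclasses.dataclass
class AnnNetworkModel:
    """One :class:`AnnGeneModel` per gene, covering genes 0..n-1 in order."""

    genes: list[AnnGeneModel]
    gene_names: list[str]

    def __post_init__(self) -> None:
        if [g.gene_index for g in self.genes] != list(range(len(self.genes))):
            raise ValueError("genes must cover 0..n-1 in order")
        if len(self.gene_names) != len(self.genes):
            raise ValueError("one name per gene required")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_parameters(self) -> int:
        """Weights + bias per gene; n*(k+1) when every gene uses full fan-in k."""
        return sum(len(g.regulators) + 1 for g in self.genes)

    def scale_table(self) -> np.ndarray:
        """(n, 2) array of per-gene (min, max) scaling ranges."""
        return np.array([[g.scale_min, g.scale_max] for g in self.genes])


def _scale(x, lo, hi):
    return SCALED_LO + (SCALED_HI - SCALED_LO) * (x - lo) / (hi - lo)


def _unscale(s, lo, hi):
    return lo + (s - SCALED_LO) * (hi - lo) / (SCALED_HI - SCALED_LO)


def ann_predict_next(
    model: AnnGeneModel,
    expressions_t: np.ndarray,
    scale_table: np.ndarray | None = None,
) -> float:
    """Predicted expression of the model's gene at t+1 given the full
    expression vector at t.

    ``scale_table`` supplies each regulator gene's (min, max) range; if
    omitted, the target gene's own range is used for every input (adequate
    only when genes share a range). Inputs are clipped into range before
    scaling.
    """
    x = np.asarray(expressions_t, dtype=float)
    if model.regulators:
        regs = np.array(model.regulators)
        if scale_table is not None:
            lo, hi = scale_table[regs, 0], scale_table[regs, 1]
        else:
            lo, hi = model.scale_min, model.scale_max
        inputs = _scale(np.clip(x[regs], lo, hi), lo, hi)
        z = model.bias + float(model.weights @ inputs)
    else:
        z = model.bias
    return float(_unscale(_sigmoid(z), model.scale_min, model.scale_max))


def _one_step_pairs(dataset: "ExpressionDataset") -> tuple[np.ndarray, np.ndarray]:
    """Pool (x(t), x(t+1)) rows over all series."""
    xs, ys = [], []
    for t, x in dataset.series:
        if t.size >= 2:
            xs.append(x[:-1])
            ys.append(x[1:])
    if not xs:
        raise ValueError("training requires at least one series with >= 2 time points")
    return np.concatenate(xs), np.concatenate(ys)


def dataset_scale_table(dataset: "ExpressionDataset", pad: float = 1e-9) -> np.ndarray:
    """Per-gene (min, max) over all series; degenerate ranges are widened."""
    vals = dataset.values_concat()
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    flat = hi - lo < pad
    lo[flat] -= 0.5
    hi[flat] += 0.5
    return np.stack([lo, hi], axis=1)


def train_ann(
    regulators: Sequence[int],
    target_gene: int,
    dataset: "ExpressionDataset",
    epochs: int = 20_000,
    learning_rate: float = 0.1,
    seed: int = 0,
    fan_in_limit: int = 4,
    scale_table: np.ndarray | None = None,
) -> tuple[AnnGeneModel, float]:
    """Fit the single-unit predictor for ``target_gene`` given a fixed
    regulator subset; returns the fitted model and its final scaled-space MSE.

    Weights start from small seeded Gaussian values, so the result is
    deterministic per seed.
    """
    regulators = tuple(int(r) for r in regulators)
    if len(regulators) > fan_in_limit:
        raise ValueError(f"{len(regulators)} regulators exceed fan-in limit {fan_in_limit}")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if scale_table is None:
        scale_table = dataset_scale_table(dataset)

    x_t, x_t1 = _one_step_pairs(dataset)
    lo_t, hi_t = scale_table[target_gene]
    y = _scale(np.clip(x_t1[:, target_gene], lo_t, hi_t), lo_t, hi_t)
    if regulators:
        regs = np.array(regulators)
        lo, hi = scale_table[regs, 0], scale_table[regs, 1]
        X = _scale(np.clip(x_t[:, regs], lo, hi), lo, hi)
    else:
        X = np.zeros((x_t.shape[0], 0))

    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 0.1, size=len(regulators))
    b = rng.normal(0.0, 0.1)
    n = y.size
    for _ in range(epochs):
        yhat = _sigmoid(X @ w + b)
        err = yhat - y
        delta = err * yhat * (1.0 - yhat)  # dL/dz for L = mean((yhat-y)^2)
        w -= learning_rate * (2.0 / n) * (X.T @ delta)
        b -= learning_rate * (2.0 / n) * delta.sum()
    mse = float(np.mean((_sigmoid(X @ w + b) - y) ** 2))
    model = AnnGeneModel(
        gene_index=int(target_gene),
        regulators=regulators,
        weights=w,
        bias=float(b),
        scale_min=float(lo_t),
        scale_max=float(hi_t),
    )
    return model, mse


def simulate_ann(network: AnnNetworkModel, x0: np.ndarray, n_steps: int) -> np.ndarray:
    """Free-running iteration: row t+1 is the genewise one-step prediction
    from row t. Returns an (n_steps + 1) x n trajectory starting at ``x0``."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    table = network.scale_table()
    out = np.empty((n_steps + 1, network.n))
    out[0] = np.asarray(x0, dtype=float)
    for t in range(n_steps):
        out[t + 1] = [ann_predict_next(g, out[t], table) for g in network.genes]
    return out
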
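"""Evaluation criteria for inferred regulatory models.

Implements the comparison criteria the benchmark scores algorithms on:
goodness of data fit (MSE between data and model output), parameter quality
(MSE between inferred and true parameters, per parameter or per gene),
qualitative interaction recovery (sensitivity/specificity over all ordered
gene pairs), robustness over repeated runs (parameter variances), and
box-plot run summaries with notches and trimmed means.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Sequence

import numpy as np

from .ann_model import AnnNetworkModel
from .datasets_io import ExpressionDataset
from .ssystem import SSystemModel

__all__ = [
    "EdgeSet",
    "RunSummary",
    "data_mse",
    "parameter_mse",
    "interactions_from_model",
    "sensitivity_specificity",
    "robustness_variance",
    "summarize_runs",
]

#: Operational "larger than zero" threshold for interaction identification.
DEFAULT_ZERO_TOL = 1e-8

EdgeSet = set  # of (regulator, target) int pairs


def data_mse(predicted: Sequence[np.ndarray] | np.ndarray, observed: ExpressionDataset) -> float:
    """Mean squared residual between model output and data, over every gene,
    time point and series.

    ``predicted`` is one trajectory matrix per series (or a single matrix for
    a one-series dataset), aligned with the dataset's time stamps.
    """
    if isinstance(predicted, np.ndarray):
        predicted = [predicted]
    if len(predicted) != len(observed.series):
        raise ValueError("one predicted trajectory per series required")
    sq_sum = 0.0
    count = 0
    for pred, (t, x) in zip(predicted, observed.series):
        pred = np.asarray(pred, dtype=float)
        if pred.shape != x.shape:
            raise ValueError(f"shape mismatch: predicted {pred.shape}, observed {x.shape}")
        sq_sum += float(np.sum((pred - x) ** 2))
        count += x.size
    return sq_sum / count


def parameter_mse(
    truth: SSystemModel,
    inferred: SSystemModel,
    mode: Literal["per_parameter", "per_gene"] = "per_parameter",
) -> float:
    """Squared parameter error, averaged per parameter or per gene.

    ``per_gene`` divides the total squared error over all alpha/beta/g/h
    entries by n instead of by the parameter count 2n + 2n^2 — the size-
    comparable convention for sparse networks of similar connectivity, where
    a per-parameter average would be dominated by the many true zeros.
    """
    if truth.n != inferred.n:
        raise ValueError("models must have the same gene count")
    total = float(np.sum((truth.parameter_vector() - inferred.parameter_vector()) ** 2))
    if mode == "per_parameter":
        return total / truth.n_parameters
    if mode == "per_gene":
        return total / truth.n
    raise ValueError(f"unknown mode {mode!r}")


def interactions_from_model(model, zero_tol: float = DEFAULT_ZERO_TOL) -> EdgeSet:
    """Identified interactions: ordered pairs (regulator j, target i).

    An interaction is identified when the corresponding parameter magnitude
    exceeds ``zero_tol``: for S-Systems, |g_ij| or |h_ij| (union convention);
    for ANN networks, a regulator with |weight| above the tolerance.
    Self-loops are ordinary pairs.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    edges: EdgeSet = set()
    if isinstance(model, SSystemModel):
        mask = (np.abs(model.g) > zero_tol) | (np.abs(model.h) > zero_tol)
        for i, j in zip(*np.nonzero(mask)):
            edges.add((int(j), int(i)))
    elif isinstance(model, AnnNetworkModel):
        for gm in model.genes:
            for r, w in zip(gm.regulators, gm.weights):
                if abs(w) > zero_tol:
                    edges.add((int(r), int(gm.gene_index)))
    else:
        raise TypeError(f"unsupported model {type(model).__name__}")
    return edges


def sensitivity_specificity(
    truth: EdgeSet,
    inferred: EdgeSet,
    n_genes: int,
    include_self_loops: bool = True,
) -> tuple[float, float]:
    """Edge-recovery sensitivity TP/(TP+FN) and specificity TN/(TN+FP) over
    all ordered gene pairs (n^2 with self-loops, n^2 - n without).

    Degenerate denominators (no true edges / no true non-edges) return 1.0,
    as no error of that kind is possible.
    """
    pairs = {
        (j, i)
        for j in range(n_genes)
        for i in range(n_genes)
        if include_self_loops or i != j
    }
    truth = set(truth) & pairs
    inferred = set(inferred) & pairs
    tp = len(truth & inferred)
    fn = len(truth - inferred)
    fp = len(inferred - truth)
    tn = len(pairs) - tp - fn - fp
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return sens, spec


def robustness_variance(models: Sequence[SSystemModel]) -> tuple[float, float]:
    """Average per-entry variance across repeated runs, reported separately
    for kinetic orders (g, h) and rate constants (alpha, beta).

    Sample variance (ddof=1) per entry, averaged over the 2n^2 kinetic-order
    entries and the 2n rate-constant entries respectively.
    """
    if len(models) < 2:
        raise ValueError("robustness requires at least 2 runs")
    n = models[0].n
    if any(m.n != n for m in models):
        raise ValueError("all runs must share the model shape")
    orders = np.array([np.concatenate([m.g.ravel(), m.h.ravel()]) for m in models])
    rates = np.array([np.concatenate([m.alpha, m.beta]) for m in models])
    return (
        float(np.mean(np.var(orders, axis=0, ddof=1))),
        float(np.mean(np.var(rates, axis=0, ddof=1))),
    )


@dataclasses.dataclass
class RunSummary:
    """Notched-box-plot statistics over one result set."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    notch_lo: float
    notch_hi: float
    mean: float
    trimmed_mean: float
    trim: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_runs(values: Iterable[float], trim: int = 0) -> RunSummary:
    """Box-plot summary of repeated-run values.

    Quartiles use linear interpolation; the notch is median +/- 1.57*IQR/sqrt(n),
    reduced to the quartile limits whenever it exceeds them. ``trim`` drops
    that many best and worst values before averaging (trimmed mean).
    """
    vals = np.sort(np.asarray(list(values), dtype=float))
    n = vals.size
    if n < 1:
        raise ValueError("no values to summarise")
    if trim < 0 or 2 * trim >= n:
        raise ValueError(f"cannot trim {trim} from each end of {n} values")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    half = 1.57 * (q3 - q1) / np.sqrt(n)
    notch_lo = max(med - half, q1)
    notch_hi = min(med + half, q3)
    trimmed = vals[trim : n - trim] if trim else vals
    return RunSummary(
        n=n,
        min=float(vals[0]),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(vals[-1]),
        notch_lo=float(notch_lo),
        notch_hi=float(notch_hi),
        mean=float(vals.mean()),
        trimmed_mean=float(trimmed.mean()),
        trim=trim,
    )
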
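"""S-System regulatory models and their numerical simulation.

An S-System describes the expression level x_i of each of n genes by a
power-law ODE::

    dx_i/dt = alpha_i * prod_j x_j**g_ij  -  beta_i * prod_j x_j**h_ij

The first (synthesis) and second (degradation) terms are each modulated by
every gene in the network through the kinetic orders g_ij and h_ij; alpha_i
and beta_i are the basal synthesis and degradation rate constants.
Self-regulation enters through the diagonal entries g_ii / h_ii.

Simulation uses fixed-step classical Runge-Kutta 4. Because candidate
parameter sets proposed by evolutionary search routinely explode, integration
never raises on divergence: the trajectory is truncated, held at its last
valid state and a flag is returned, so fitness functions can penalise the
individual instead of crashing the run.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .datasets_io import ExpressionDataset

__all__ = [
    "SSystemModel",
    "SolverConfig",
    "SimulationResult",
    "ssystem_rhs",
    "simulate_ssystem",
    "simulate_decoupled",
    "STATE_FLOOR",
]

#: States are clamped to this floor before power evaluation: negative kinetic
#: orders make the power law singular at 0 and non-integer orders make it
#: complex below 0.
STATE_FLOOR = 1e-6


@dataclasses.dataclass
class SSystemModel:
    """Parameter container for an n-gene S-System.

    ``alpha``/``beta`` are length-n non-negative rate-constant vectors and
    ``g``/``h`` are the n x n synthesis / degradation kinetic-order matrices
    (entry ``[i, j]`` = influence of gene j on gene i).
    """

    alpha: np.ndarray
    beta: np.ndarray
    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = self.alpha.shape[0]
        if self.beta.shape != (n,) or self.g.shape != (n, n) or self.h.shape != (n, n):
            raise ValueError(
                f"inconsistent shapes: alpha {self.alpha.shape}, beta "
                f"{self.beta.shape}, g {self.g.shape}, h {self.h.shape}"
            )
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValueError("rate constants must be non-negative")
        for name, m in (("alpha", self.alpha), ("beta", self.beta), ("g", self.g), ("h", self.h)):
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_parameters(self) -> int:
        """Total parameter count 2n + 2n^2 (rate constants + kinetic orders)."""
        return 2 * self.n + 2 * self.n * self.n

    def parameter_vector(self) -> np.ndarray:
        """Flatten as [alpha, beta, g.ravel(), h.ravel()] (search encoding)."""
        return np.concatenate([self.alpha, self.beta, self.g.ravel(), self.h.ravel()])

    @classmethod
    def from_parameter_vector(cls, theta: np.ndarray, n: int) -> "SSystemModel":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (2 * n + 2 * n * n,):
            raise ValueError(f"expected {2 * n + 2 * n * n} parameters for n={n}")
        return cls(
            alpha=theta[:n],
            beta=theta[n : 2 * n],
            g=theta[2 * n : 2 * n + n * n].reshape(n, n),
            h=theta[2 * n + n * n :].reshape(n, n),
        )

    @classmethod
    def _from_vector_unchecked(cls, theta: np.ndarray, n: int) -> "SSystemModel":
        # hot-path constructor for fitness evaluation: candidates come from
        # bounded search spaces, so the invariant checks are skipped
        m = object.__new__(cls)
        m.alpha = theta[:n]
        m.beta = theta[n : 2 * n]
        m.g = theta[2 * n : 2 * n + n * n].reshape(n, n)
        m.h = theta[2 * n + n * n :].reshape(n, n)
        return m


@dataclasses.dataclass
class SolverConfig:
    """Fixed-step RK4 settings.

    ``step`` is the maximum internal step (each inter-sample interval is
    subdivided into equal steps no larger than this); ``divergence_cap`` is
    the state magnitude beyond which integration is truncated and flagged.
    """

    step: float = 0.01
    divergence_cap: float = 1e6

    def __post_init__(self) -> None:
        if not (self.step > 0 and np.isfinite(self.step)):
            raise ValueError(f"step must be a positive finite number, got {self.step}")
        if not (self.divergence_cap > 0):
            raise ValueError("divergence_cap must be positive")


@dataclasses.dataclass
class SimulationResult:
    times: np.ndarray
    trajectory: np.ndarray  # len(times) x n, finite, >= STATE_FLOOR
    diverged: bool
    truncation_index: int  # first output row affected by divergence (len(times) if none)


def ssystem_rhs(model: SSystemModel, state: np.ndarray) -> np.ndarray:
    """Time derivative of the expression vector at ``state`` (all entries > 0)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n,):
        raise ValueError(f"state shape {state.shape} does not match n={model.n}")
    if np.any(state <= 0):
        raise ValueError("S-System right-hand side requires strictly positive state")
    return _rhs_clamped(model, state)


def _rhs_clamped(model: SSystemModel, state: np.ndarray) -> np.ndarray:
    # prod_j x_j**g_ij computed as exp(g @ log x); state pre-clamped > 0
    logx = np.log(state)
    return model.alpha * np.exp(model.g @ logx) - model.beta * np.exp(model.h @ logx)


def _rk4_step(model: SSystemModel, x: np.ndarray, h: float) -> np.ndarray:
    floor = STATE_FLOOR
    k1 = _rhs_clamped(model, x)
    k2 = _rhs_clamped(model, np.maximum(x + 0.5 * h * k1, floor))
    k3 = _rhs_clamped(model, np.maximum(x + 0.5 * h * k2, floor))
    k4 = _rhs_clamped(model, np.maximum(x + h * k3, floor))
    return np.maximum(x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), floor)


def simulate_ssystem(
    model: SSystemModel,
    x0: np.ndarray,
    times: np.ndarray,
    solver_cfg: SolverConfig | None = None,
) -> SimulationResult:
    """Integrate the full coupled system, reporting rows at ``times``.

    ``trajectory[0]`` equals ``x0``; rows are clamped to ``STATE_FLOOR``.
    On blow-up (any component above the divergence cap or non-finite) the
    remaining rows repeat the last valid state and ``diverged`` is set.
    """
    cfg = solver_cfg or SolverConfig()
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial state must be strictly positive")
    if times.size < 1 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ValueError("times must be non-empty and strictly increasing")

    n_out = times.size
    out = np.empty((n_out, model.n))
    out[0] = np.maximum(x0, STATE_FLOOR)
    x = out[0].copy()
    diverged = False
    trunc = n_out
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for k in range(1, n_out):
            dt = times[k] - times[k - 1]
            n_sub = max(1, int(np.ceil(dt / cfg.step - 1e-12)))
            h = dt / n_sub
            for _ in range(n_sub):
                x = _rk4_step(model, x, h)
                if not np.all(np.isfinite(x)) or np.any(np.abs(x) > cfg.divergence_cap):
                    diverged = True
                    break
            if diverged:
                trunc = k
                x = np.clip(np.nan_to_num(out[k - 1], nan=cfg.divergence_cap), STATE_FLOOR, cfg.divergence_cap)
                out[k:] = x
                break
            out[k] = x
    return SimulationResult(times=times, trajectory=out, diverged=diverged, truncation_index=trunc)


class DecoupledGrid:
    """Pre-computed integration grid for one-gene-at-a-time simulation.

    For the decoupled (divide-and-conquer) fitness convention, gene i's ODE is
    integrated alone while the other genes' trajectories are pinned to the
    observed data, interpolated piecewise-linearly between sample times. This
    object caches, per series, the log-expressions of all genes at every RK4
    stage time so repeated candidate evaluations cost one small matmul plus a
    scalar integration loop.
    """

    def __init__(self, dataset: "ExpressionDataset", step: float = 0.01):
        self.step = step
        self.n_genes = dataset.n_genes
        self.series = []
        for t, x in dataset.series:
            n_sub = np.maximum(1, np.ceil(np.diff(t) / step - 1e-12).astype(int)) if t.size > 1 else np.array([], dtype=int)
            h = np.diff(t) / n_sub if t.size > 1 else np.array([])
            # stage times: for each sub-step, (t0, t0+h/2, t0+h); collect unique grid
            stage_times = []
            for k in range(t.size - 1):
                t0 = t[k]
                for s in range(n_sub[k]):
                    a = t0 + s * h[k]
                    stage_times.extend((a, a + 0.5 * h[k], a + h[k]))
            stage_times = np.array(stage_times) if stage_times else np.empty(0)
            interp = np.empty((stage_times.size, dataset.n_genes))
            for j in range(dataset.n_genes):
                interp[:, j] = np.interp(stage_times, t, x[:, j])
            log_interp = np.log(np.maximum(interp, STATE_FLOOR))
            self.series.append(
                {
                    "times": t,
                    "values": x,
                    "n_sub": n_sub,
                    "h": h,
                    "log_interp": log_interp,
                }
            )


def simulate_decoupled(
    model: SSystemModel,
    dataset: "ExpressionDataset",
    gene_index: int,
    solver_cfg: SolverConfig | None = None,
    grid: DecoupledGrid | None = None,
) -> list[np.ndarray]:
    """Predict gene ``gene_index``'s series with all other genes held at the data.

    Returns one predicted vector per series, aligned with the dataset's time
    stamps (first entry = observed initial value). Divergence is handled as in
    :func:`simulate_ssystem`: the prediction is held at the cap.
    """
    cfg = solver_cfg or SolverConfig()
    i = gene_index
    if not (0 <= i < model.n) or dataset.n_genes != model.n:
        raise ValueError("gene index / dataset incompatible with model")
    if grid is None:
        grid = DecoupledGrid(dataset, step=cfg.step)

    gi = model.g[i].copy()
    hi = model.h[i].copy()
    g_ii, h_ii = gi[i], hi[i]
    gi[i] = 0.0
    hi[i] = 0.0
    alpha_i, beta_i = model.alpha[i], model.beta[i]
    cap = cfg.divergence_cap

    out = []
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for ser in grid.series:
            t, x = ser["times"], ser["values"]
            # log-linear contribution of the observed genes at each RK4 stage
            cg = ser["log_interp"] @ gi
            ch = ser["log_interp"] @ hi
            pred = np.empty(t.size)
            pred[0] = max(x[0, i], STATE_FLOOR)
            xi = pred[0]
            stage = 0
            diverged = False
            for k in range(t.size - 1):
                for _ in range(ser["n_sub"][k]):
                    hstep = ser["h"][k]
                    lx = np.log(xi)
                    k1 = alpha_i * np.exp(cg[stage] + g_ii * lx) - beta_i * np.exp(ch[stage] + h_ii * lx)
                    y = max(xi + 0.5 * hstep * k1, STATE_FLOOR)
                    ly = np.log(y)
                    k2 = alpha_i * np.exp(cg[stage + 1] + g_ii * ly) - beta_i * np.exp(ch[stage + 1] + h_ii * ly)
                    y = max(xi + 0.5 * hstep * k2, STATE_FLOOR)
                    ly = np.log(y)
                    k3 = alpha_i * np.exp(cg[stage + 1] + g_ii * ly) - beta_i * np.exp(ch[stage + 1] + h_ii * ly)
                    y = max(xi + hstep * k3, STATE_FLOOR)
                    ly = np.log(y)
                    k4 = alpha_i * np.exp(cg[stage + 2] + g_ii * ly) - beta_i * np.exp(ch[stage + 2] + h_ii * ly)
                    xi = max(xi + (hstep / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), STATE_FLOOR)
                    stage += 3
                    if not np.isfinite(xi) or abs(xi) > cap:
                        diverged = True
                        xi = cap
                        break
                pred[k + 1] = xi
                if diverged:
                    pred[k + 1 :] = cap
                    break
            out.append(pred)
    return out
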
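import numpy as np
import pytest

from grn_evobench.datasets_io import ExpressionDataset
from grn_evobench.ssystem import SolverConfig, SSystemModel, simulate_ssystem
from grn_evobench.synthetic import BenchmarkSpec, generate_benchmark

#: fast integration settings shared by the optimiser-heavy tests: the
#: benchmark fixtures sample every 0.05 time units, so one RK4 step per
#: sampling interval
FAST_SOLVER = SolverConfig(step=0.05)


@pytest.fixture(scope="session")
def ss2():
    """2-gene S-System recovery fixture: (spec, truth model, noiseless data).

    Mirrors the small-scale comparison setting: a sparse 2-gene network,
    20 time points split over two series from different initial states.
    """
    spec = BenchmarkSpec(
        n_genes=2, connectivity=(1, 1), seed=3, n_time_points=20, n_series=2
    )
    truth, edges, data = generate_benchmark(spec)
    return spec, truth, data


@pytest.fixture(scope="session")
def ann2():
    """2-gene ANN recovery fixture (truth network + one-step data)."""
    spec = BenchmarkSpec(
        n_genes=2, connectivity=(1, 1), model_type="ann", seed=5,
        n_time_points=20, n_series=2,
    )
    truth, edges, data = generate_benchmark(spec)
    return spec, truth, data


@pytest.fixture(scope="session")
def decay1():
    """1-gene pure-decay fixture: dx/dt = -beta * x^h with known beta, h."""
    truth = SSystemModel(alpha=[0.0], beta=[1.5], g=[[0.0]], h=[[0.8]])
    t = np.linspace(0.0, 2.0, 15)
    res = simulate_ssystem(truth, [2.0], t, SolverConfig(step=0.01))
    data = ExpressionDataset(series=[(t, res.trajectory)], gene_names=["G1"])
    return truth, data


@pytest.fixture(scope="session")
def ss5():
    """5-gene S-System benchmark (60 points, 4 series) for protocol tests."""
    spec = BenchmarkSpec(n_genes=5, seed=1)
    truth, edges, data = generate_benchmark(spec)
    return spec, truth, data
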
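import numpy as np
import pytest
from scipy.integrate import solve_ivp

from grn_evobench.datasets_io import ExpressionDataset
from grn_evobench.ssystem import (
    STATE_FLOOR,
    SolverConfig,
    SSystemModel,
    simulate_decoupled,
    simulate_ssystem,
    ssystem_rhs,
)


def rhs_oracle(model: SSystemModel, x: np.ndarray) -> np.ndarray:
    """Naive scalar-loop evaluation of the power-law rate equations."""
    n = model.n
    out = np.zeros(n)
    for i in range(n):
        synth, degr = model.alpha[i], model.beta[i]
        for j in range(n):
            synth *= x[j] ** model.g[i, j]
            degr *= x[j] ** model.h[i, j]
        out[i] = synth - degr
    return out


def random_model(rng: np.random.Generator, n: int) -> SSystemModel:
    return SSystemModel(
        alpha=rng.uniform(0, 10, n),
        beta=rng.uniform(0, 10, n),
        g=rng.uniform(-2, 2, (n, n)),
        h=rng.uniform(-2, 2, (n, n)),
    )


class TestRhs:
    def test_balanced_model_is_stationary(self):
        m = SSystemModel(alpha=[1.0], beta=[1.0], g=[[0.0]], h=[[0.0]])
        assert ssystem_rhs(m, np.array([5.0])) == pytest.approx(0.0)

    def test_pure_linear_degradation(self):
        m = SSystemModel(alpha=[0.0], beta=[1.0], g=[[0.0]], h=[[1.0]])
        assert ssystem_rhs(m, np.array([2.0]))[0] == pytest.approx(-2.0)

    def test_two_gene_case_matches_scalar_oracle(self):
        m = SSystemModel(
            alpha=[1.0, 2.0], beta=[1.0, 1.0],
            g=[[0.0, 1.0], [0.5, 0.0]], h=np.eye(2),
        )
        x = np.array([1.0, 4.0])
        np.testing.assert_allclose(ssystem_rhs(m, x), rhs_oracle(m, x), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_models_match_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        m = random_model(rng, n)
        x = rng.uniform(0.1, 3.0, n)
        np.testing.assert_allclose(ssystem_rhs(m, x), rhs_oracle(m, x), rtol=1e-12)

    def test_nonpositive_state_rejected(self):
        m = SSystemModel(alpha=[1.0], beta=[1.0], g=[[0.0]], h=[[1.0]])
        with pytest.raises(ValueError):
            ssystem_rhs(m, np.array([0.0]))


class TestSimulate:
    def test_steady_model_stays_constant(self):
        m = SSystemModel(
            alpha=[2.0, 3.0], beta=[2.0, 3.0],
            g=[[0.1, 0.2], [0.0, 0.3]], h=[[0.1, 0.2], [0.0, 0.3]],
        )
        x0 = np.array([1.3, 0.7])
        res = simulate_ssystem(m, x0, np.linspace(0, 1, 11))
        assert not res.diverged
        np.testing.assert_allclose(res.trajectory, np.tile(x0, (11, 1)), rtol=1e-9)

    def test_exponential_decay_matches_closed_form(self):
        # dx/dt = -x  =>  x(t) = e^{-t}
        m = SSystemModel(alpha=[0.0], beta=[1.0], g=[[0.0]], h=[[1.0]])
        t = np.arange(0.0, 5.0 + 1e-9, 0.1)
        res = simulate_ssystem(m, [1.0], t, SolverConfig(step=0.01))
        assert np.max(np.abs(res.trajectory[:, 0] - np.exp(-t))) < 1e-6

    def test_blowup_sets_divergence_flag(self):
        m = SSystemModel(alpha=[1e5], beta=[0.0], g=[[2.0]], h=[[0.0]])
        res = simulate_ssystem(m, [2.0], np.linspace(0, 10, 20))
        assert res.diverged
        assert res.truncation_index < 20
        assert np.all(np.isfinite(res.trajectory))
        assert np.all(res.trajectory >= STATE_FLOOR)

    def test_rk4_order_of_convergence(self):
        # halving the step should shrink the error by about 2^4
        m = SSystemModel(alpha=[0.0], beta=[1.0], g=[[0.0]], h=[[1.0]])
        t = np.array([0.0, 1.0])
        exact = np.exp(-1.0)
        errs = []
        for step in (0.1, 0.05, 0.025):
            res = simulate_ssystem(m, [1.0], t, SolverConfig(step=step))
            errs.append(abs(res.trajectory[1, 0] - exact))
        assert errs[0] / errs[1] == pytest.approx(16, rel=0.3)
        assert errs[1] / errs[2] == pytest.approx(16, rel=0.3)

    def test_agrees_with_scipy_reference_integrator(self):
        rng = np.random.default_rng(7)
        m = SSystemModel(
            alpha=rng.uniform(1, 5, 3), beta=rng.uniform(1, 5, 3),
            g=rng.uniform(-0.5, 0.5, (3, 3)), h=0.5 * np.eye(3) + rng.uniform(-0.2, 0.2, (3, 3)),
        )
        x0 = rng.uniform(0.5, 2.0, 3)
        t = np.linspace(0, 2, 9)
        mine = simulate_ssystem(m, x0, t, SolverConfig(step=0.005))
        ref = solve_ivp(
            lambda _, x: ssystem_rhs(m, np.maximum(x, STATE_FLOOR)),
            (0, 2), x0, t_eval=t, rtol=1e-10, atol=1e-12,
        )
        assert not mine.diverged
        np.testing.assert_allclose(mine.trajectory, ref.y.T, rtol=1e-6, atol=1e-8)

    def test_trajectory_starts_at_x0(self):
        m = SSystemModel(alpha=[1.0], beta=[1.0], g=[[0.0]], h=[[1.0]])
        res = simulate_ssystem(m, [0.42], np.linspace(0, 1, 5))
        assert res.trajectory[0, 0] == pytest.approx(0.42)

    def test_invalid_solver_config_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(step=0.0)
        with pytest.raises(ValueError):
            SolverConfig(step=0.1, divergence_cap=-1)


class TestDecoupled:
    def _model_and_data(self):
        rng = np.random.default_rng(11)
        m = SSystemModel(
            alpha=[3.0, 2.0], beta=[2.5, 3.5],
            g=[[0.0, 0.8], [0.0, 0.0]], h=[[1.0, 0.0], [-0.5, 1.2]],
        )
        x0 = rng.uniform(0.5, 2.0, 2)
        # dense sampling: the decoupled mode interpolates the *observed*
        # neighbours piecewise-linearly, so its self-consistency error is
        # dominated by the sampling interval, not the integrator step
        t = np.linspace(0, 1.5, 76)
        res = simulate_ssystem(m, x0, t, SolverConfig(step=0.005))
        assert not res.diverged
        data = ExpressionDataset(series=[(t, res.trajectory)], gene_names=["G1", "G2"])
        return m, data

    def test_generating_model_reproduces_its_own_data(self):
        # self-consistency: decoupled prediction of each gene of the true
        # model on its own noiseless output equals that output
        m, data = self._model_and_data()
        for gene in range(2):
            pred = simulate_decoupled(m, data, gene, SolverConfig(step=0.005))[0]
            np.testing.assert_allclose(pred, data.series[0][1][:, gene], rtol=2e-4, atol=2e-5)

    def test_matches_scalar_rk4_hand_stepping(self):
        # gene 0 depends only on observed gene 1 held piecewise linear:
        # integrate the scalar ODE by explicit RK4 with the same grid
        m, data = self._model_and_data()
        t, x = data.series[0]
        cfg = SolverConfig(step=0.05)
        pred = simulate_decoupled(m, data, 0, cfg)[0]

        def f(tt, x0val):
            x1 = np.interp(tt, t, x[:, 1])
            x1 = max(x1, STATE_FLOOR)
            return m.alpha[0] * x1**0.8 - m.beta[0] * x0val**1.0

        xi = x[0, 0]
        hand = [xi]
        for k in range(t.size - 1):
            dt = t[k + 1] - t[k]
            h = dt  # dt = 0.1 spacing, step cap 0.05 -> 2 substeps
            n_sub = int(np.ceil(dt / cfg.step - 1e-12))
            h = dt / n_sub
            for s in range(n_sub):
                t0 = t[k] + s * h
                k1 = f(t0, xi)
                k2 = f(t0 + h / 2, max(xi + h / 2 * k1, STATE_FLOOR))
                k3 = f(t0 + h / 2, max(xi + h / 2 * k2, STATE_FLOOR))
                k4 = f(t0 + h, max(xi + h * k3, STATE_FLOOR))
                xi = max(xi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), STATE_FLOOR)
            hand.append(xi)
        np.testing.assert_allclose(pred, hand, rtol=1e-10)

    def test_decoupled_close_to_coupled_on_noiseless_data(self):
        m, data = self._model_and_data()
        t, x = data.series[0]
        coupled = simulate_ssystem(m, x[0], t, SolverConfig(step=0.005)).trajectory
        for gene in range(2):
            pred = simulate_decoupled(m, data, gene, SolverConfig(step=0.005))[0]
            np.testing.assert_allclose(pred, coupled[:, gene], rtol=2e-4, atol=2e-5)
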
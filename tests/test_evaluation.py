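import numpy as np
import pytest

from grn_evobench.datasets_io import ExpressionDataset
from grn_evobench.evaluation import (
    data_mse,
    interactions_from_model,
    parameter_mse,
    robustness_variance,
    sensitivity_specificity,
    summarize_runs,
)
from grn_evobench.ssystem import SSystemModel


def make_model(n, rng=None, sparse=False):
    rng = rng or np.random.default_rng(0)
    g = rng.uniform(-2, 2, (n, n))
    h = rng.uniform(-2, 2, (n, n))
    if sparse:
        g[rng.random((n, n)) < 0.6] = 0.0
        h[rng.random((n, n)) < 0.6] = 0.0
    return SSystemModel(alpha=rng.uniform(0, 5, n), beta=rng.uniform(0, 5, n), g=g, h=h)


class TestDataMse:
    def _ds(self, x, t=None):
        x = np.asarray(x, dtype=float)
        t = np.arange(float(x.shape[0])) if t is None else t
        return ExpressionDataset(series=[(t, x)], gene_names=[f"g{i}" for i in range(x.shape[1])])

    def test_perfect_prediction_is_zero(self):
        ds = self._ds([[1.0], [2.0]])
        assert data_mse([ds.series[0][1]], ds) == 0.0

    def test_hand_arithmetic(self):
        ds = self._ds([[1.0], [2.0]])
        assert data_mse([np.array([[2.0], [2.0]])], ds) == pytest.approx(0.5)

    def test_invariant_under_series_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 2, (4, 2)), rng.uniform(0, 2, (6, 2))
        pa, pb = a + 0.1, b - 0.2
        ds1 = ExpressionDataset(series=[(np.arange(4.0), a), (np.arange(6.0), b)], gene_names=["x", "y"])
        ds2 = ExpressionDataset(series=[(np.arange(6.0), b), (np.arange(4.0), a)], gene_names=["x", "y"])
        assert data_mse([pa, pb], ds1) == pytest.approx(data_mse([pb, pa], ds2))

    def test_shape_mismatch_rejected(self):
        ds = self._ds([[1.0], [2.0]])
        with pytest.raises(ValueError):
            data_mse([np.ones((3, 1))], ds)


class TestParameterMse:
    def test_identical_models_zero(self):
        m = make_model(3)
        assert parameter_mse(m, m) == 0.0

    def test_single_entry_difference_both_modes(self):
        # n=2 has 2n + 2n^2 = 12 parameters; one entry off by 2 gives
        # 4/12 per parameter and 4/2 per gene
        m1 = make_model(2)
        m2 = SSystemModel(alpha=m1.alpha.copy(), beta=m1.beta, g=m1.g, h=m1.h)
        m2.alpha = m1.alpha.copy()
        m2.alpha[0] += 2.0
        assert parameter_mse(m1, m2) == pytest.approx(4 / 12)
        assert parameter_mse(m1, m2, mode="per_gene") == pytest.approx(4 / 2)

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_mode_ratio_identity(self, n):
        rng = np.random.default_rng(n)
        m1, m2 = make_model(n, rng), make_model(n, rng)
        per_param = parameter_mse(m1, m2)
        per_gene = parameter_mse(m1, m2, mode="per_gene")
        assert per_gene / per_param == pytest.approx(m1.n_parameters / n)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            parameter_mse(make_model(2), make_model(3))


class TestInteractions:
    def test_all_zero_matrices_give_empty_set(self):
        m = SSystemModel(alpha=[1, 1], beta=[1, 1], g=np.zeros((2, 2)), h=np.zeros((2, 2)))
        assert interactions_from_model(m) == set()

    def test_single_entry(self):
        g = np.zeros((2, 2))
        g[0, 1] = 0.5  # gene 2 (index 1) regulates gene 1 (index 0)
        m = SSystemModel(alpha=[1, 1], beta=[1, 1], g=g, h=np.zeros((2, 2)))
        assert interactions_from_model(m) == {(1, 0)}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        m = make_model(int(rng.integers(2, 8)), rng, sparse=True)
        tol = 1e-8
        expected = set()
        for i in range(m.n):
            for j in range(m.n):
                if abs(m.g[i, j]) > tol or abs(m.h[i, j]) > tol:
                    expected.add((j, i))
        assert interactions_from_model(m, tol) == expected


class TestSensitivitySpecificity:
    def test_perfect_recovery(self):
        edges = {(0, 1), (1, 1)}
        assert sensitivity_specificity(edges, edges, 3) == (1.0, 1.0)

    def test_empty_inference(self):
        assert sensitivity_specificity({(0, 1)}, set(), 3) == (0.0, 1.0)

    def test_three_gene_enumeration(self):
        # truth {1->2, 2->2}, inferred {1->2, 3->1} with 1-based labels:
        # TP=1, FN=1, FP=1, TN=6 over the 9 ordered pairs
        truth = {(0, 1), (1, 1)}
        inferred = {(0, 1), (2, 0)}
        sens, spec = sensitivity_specificity(truth, inferred, 3)
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(6 / 7)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_confusion_matrix_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        pairs = [(j, i) for j in range(n) for i in range(n)]
        truth = {p for p in pairs if rng.random() < 0.3}
        inferred = {p for p in pairs if rng.random() < 0.3}
        tp = sum(1 for p in pairs if p in truth and p in inferred)
        fn = sum(1 for p in pairs if p in truth and p not in inferred)
        fp = sum(1 for p in pairs if p not in truth and p in inferred)
        tn = len(pairs) - tp - fn - fp
        expect = (tp / (tp + fn) if tp + fn else 1.0, tn / (tn + fp) if tn + fp else 1.0)
        assert sensitivity_specificity(truth, inferred, n) == pytest.approx(expect)

    def test_gene_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        n = 6
        truth = {(int(j), int(i)) for j, i in rng.integers(0, n, (8, 2))}
        inferred = {(int(j), int(i)) for j, i in rng.integers(0, n, (8, 2))}
        perm = rng.permutation(n)
        t2 = {(perm[j], perm[i]) for j, i in truth}
        i2 = {(perm[j], perm[i]) for j, i in inferred}
        assert sensitivity_specificity(truth, inferred, n) == pytest.approx(
            sensitivity_specificity(t2, i2, n)
        )


class TestRobustness:
    def test_identical_runs_zero_variance(self):
        m = make_model(3)
        ko, rc = robustness_variance([m, m, m])
        assert ko == pytest.approx(0.0, abs=1e-25)
        assert rc == pytest.approx(0.0, abs=1e-25)

    def test_single_rate_difference(self):
        # two runs differing only in alpha_1 by 2: per-entry sample variance
        # is 2 there and 0 elsewhere, averaged over the 2n rate entries
        m1 = make_model(2)
        m2 = SSystemModel(alpha=m1.alpha.copy(), beta=m1.beta, g=m1.g, h=m1.h)
        m2.alpha = m1.alpha.copy()
        m2.alpha[0] += 2.0
        ko, rc = robustness_variance([m1, m2])
        assert ko == 0.0
        assert rc == pytest.approx(2.0 / 4)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        models = [make_model(3, rng) for _ in range(5)]
        assert robustness_variance(models) == pytest.approx(robustness_variance(models[::-1]))

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            robustness_variance([make_model(2)])


class TestSummarizeRuns:
    def test_constant_values(self):
        s = summarize_runs([2.0] * 8)
        assert s.min == s.q1 == s.median == s.q3 == s.max == 2.0
        assert s.notch_lo == s.notch_hi == 2.0

    def test_trimmed_mean_hand_arithmetic(self):
        s = summarize_runs(range(1, 21), trim=2)
        assert s.trimmed_mean == pytest.approx(10.5)  # mean of 3..18
        assert s.mean == pytest.approx(10.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_notches_clipped_to_quartiles(self, seed):
        rng = np.random.default_rng(seed)
        s = summarize_runs(rng.exponential(1.0, 7))
        assert s.q1 <= s.notch_lo <= s.median <= s.notch_hi <= s.q3

    def test_over_trimming_rejected(self):
        with pytest.raises(ValueError):
            summarize_runs([1.0, 2.0, 3.0], trim=2)
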
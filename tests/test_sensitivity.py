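"""Sampling designs and Saltelli estimators against analytic oracles."""

import numpy as np
import pytest
from scipy.stats import qmc

import endosig as es
from endosig.sensitivity import (SensitivityConfig, lhs_strata_check,
                                 rank_top, sample_parameter_space,
                                 sobol_first_order, sobol_second_order,
                                 SobolResult)

LO, HI = 0.2, 5.0


def to_unit(x):
    return (np.asarray(x) - LO) / (HI - LO)


def ishigami(x, a=7.0, b=0.1):
    u = to_unit(x) * 2 * np.pi - np.pi
    return np.array([np.sin(u[0]) + a * np.sin(u[1]) ** 2
                     + b * u[2] ** 4 * np.sin(u[0])])


def ishigami_analytic(a=7.0, b=0.1):
    V = 0.5 + a ** 2 / 8 + b * np.pi ** 4 / 5 + b ** 2 * np.pi ** 8 / 18
    S1 = 0.5 * (1 + b * np.pi ** 4 / 5) ** 2 / V
    S2 = (a ** 2 / 8) / V
    return S1, S2, 0.0


class TestSampling:
    def test_lhs_puts_one_sample_per_stratum(self):
        cfg = SensitivityConfig(parameters=["x"], n_base=10, seed=3)
        A, B, AB, BA = sample_parameter_space(cfg, {"x": 1.0})
        assert lhs_strata_check(A[:, 0], LO, HI)
        assert lhs_strata_check(B[:, 0], LO, HI)

    def test_same_seed_reproduces_different_seed_differs(self):
        cfg0 = SensitivityConfig(parameters=["a", "b"], n_base=16, seed=0)
        cfg0b = SensitivityConfig(parameters=["a", "b"], n_base=16, seed=0)
        cfg1 = SensitivityConfig(parameters=["a", "b"], n_base=16, seed=1)
        base = {"a": 1.0, "b": 2.0}
        A0 = sample_parameter_space(cfg0, base)[0]
        A0b = sample_parameter_space(cfg0b, base)[0]
        A1 = sample_parameter_space(cfg1, base)[0]
        np.testing.assert_array_equal(A0, A0b)
        assert not np.array_equal(A0, A1)

    def test_ab_matrices_swap_exactly_one_column(self):
        cfg = SensitivityConfig(parameters=["a", "b", "c"], n_base=8, seed=0)
        base = {"a": 1.0, "b": 1.0, "c": 1.0}
        A, B, AB, BA = sample_parameter_space(cfg, base)
        for i in range(3):
            for j in range(3):
                src = B if i == j else A
                np.testing.assert_array_equal(AB[i][:, j], src[:, j])

    def test_sobol_sequence_beats_iid_uniform_discrepancy(self):
        # 2-D, n=1024, skip 1000, leap 100 (averaged over 10 seeds)
        n, d = 1024, 2
        better = 0
        for seed in range(10):
            cfg = SensitivityConfig(parameters=["a", "b"], n_base=n,
                                    sampler="sobol_sequence", seed=seed)
            A = sample_parameter_space(cfg, {"a": 1.0, "b": 1.0})[0]
            U = to_unit(A)
            rng = np.random.default_rng(seed)
            iid = rng.uniform(size=(n, d))
            if qmc.discrepancy(U) < qmc.discrepancy(iid):
                better += 1
        assert better >= 6  # lower discrepancy on average


class TestFirstOrder:
    def test_ishigami_within_003_of_analytic_at_4096(self):
        cfg = SensitivityConfig(parameters=["x1", "x2", "x3"], n_base=4096,
                                outputs=("y",), bootstrap=200, seed=0)
        res = sobol_first_order(ishigami, cfg,
                                {k: 1.0 for k in ("x1", "x2", "x3")})
        S = [res.main_effect["y"][k][0] for k in ("x1", "x2", "x3")]
        for est, true in zip(S, ishigami_analytic()):
            assert abs(est - true) < 0.03
        assert res.n_runs == 4096 * (3 + 2)

    def test_additive_linear_model_decomposition(self):
        c = np.array([2.0, 1.0, 0.5])
        f = lambda x: np.array([float(c @ np.asarray(x))])
        cfg = SensitivityConfig(parameters=["a", "b", "cc"], n_base=4096,
                                outputs=("y",), bootstrap=100, seed=0)
        res = sobol_first_order(f, cfg, {"a": 1.0, "b": 1.0, "cc": 1.0})
        S = np.array([res.main_effect["y"][k][0] for k in ("a", "b", "cc")])
        expected = c ** 2 / (c ** 2).sum()  # equal Var(X_i)
        np.testing.assert_allclose(S, expected, atol=0.02)
        assert abs(S.sum() - 1.0) < 0.02

    def test_constant_output_flagged_degenerate(self):
        f = lambda x: np.array([1.0])
        cfg = SensitivityConfig(parameters=["a", "b"], n_base=64,
                                outputs=("y",), bootstrap=10, seed=0)
        res = sobol_first_order(f, cfg, {"a": 1.0, "b": 1.0})
        assert res.degenerate == ["y"]
        assert np.isnan(res.main_effect["y"]["a"][0])

    def test_error_shrinks_with_sample_size(self):
        errors = []
        for n in (512, 4096):
            cfg = SensitivityConfig(parameters=["x1", "x2", "x3"], n_base=n,
                                    outputs=("y",), bootstrap=10, seed=0)
            res = sobol_first_order(ishigami, cfg,
                                    {k: 1.0 for k in ("x1", "x2", "x3")})
            S = [res.main_effect["y"][k][0] for k in ("x1", "x2", "x3")]
            errors.append(sum(abs(e - t)
                              for e, t in zip(S, ishigami_analytic())))
        assert errors[-1] < errors[0]

    def test_bootstrap_ci_contains_point_estimate(self):
        cfg = SensitivityConfig(parameters=["x1", "x2", "x3"], n_base=512,
                                outputs=("y",), bootstrap=100, seed=0)
        res = sobol_first_order(ishigami, cfg,
                                {k: 1.0 for k in ("x1", "x2", "x3")})
        for s, lo, hi in res.main_effect["y"].values():
            assert lo <= s <= hi


class TestSecondOrder:
    def test_pure_product_interaction(self):
        def f(x):
            u = to_unit(x) * 2 - 1
            return np.array([u[0] * u[1]])
        cfg = SensitivityConfig(parameters=["x1", "x2"], n_base=16384,
                                outputs=("y",), bootstrap=20, seed=0)
        res = sobol_second_order(f, cfg, {"x1": 1.0, "x2": 1.0})
        s1 = res.main_effect["y"]["x1"][0]
        s2 = res.main_effect["y"]["x2"][0]
        assert abs(s1) < 0.05 and abs(s2) < 0.05
        assert abs(res.second_order["y"][0, 1] - 1.0) < 0.05
        assert res.n_runs == 16384 * (2 * 2 + 2)

    def test_additive_function_has_no_interactions(self):
        f = lambda x: np.array([2 * x[0] + 3 * x[1] + x[2]])
        cfg = SensitivityConfig(parameters=["a", "b", "c"], n_base=8192,
                                outputs=("y",), bootstrap=20, seed=0)
        res = sobol_second_order(f, cfg, {"a": 1.0, "b": 1.0, "c": 1.0})
        M = res.second_order["y"]
        off = M[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.02)

    def test_matrix_symmetric_with_zero_diagonal(self):
        f = lambda x: np.array([x[0] * x[1] + x[2]])
        cfg = SensitivityConfig(parameters=["a", "b", "c"], n_base=256,
                                outputs=("y",), bootstrap=10, seed=0)
        res = sobol_second_order(f, cfg, {"a": 1.0, "b": 1.0, "c": 1.0})
        M = res.second_order["y"]
        np.testing.assert_array_equal(M, M.T)
        assert np.all(np.diag(M) == 0.0)


class TestRanking:
    def _result(self, estimates):
        return SobolResult(parameters=list(estimates), outputs=["y"],
                           main_effect={"y": {k: (v, v, v)
                                              for k, v in estimates.items()}},
                           n_runs=0)

    def test_known_ordering_returned_exactly(self):
        res = self._result({"a": 0.1, "b": 0.5, "c": 0.3})
        assert [k for k, _ in rank_top(res, "y", 3)] == ["b", "c", "a"]

    def test_ties_break_lexicographically(self):
        res = self._result({"beta": 0.5, "alpha": 0.5, "gamma": 0.1})
        assert [k for k, _ in rank_top(res, "y", 2)] == ["alpha", "beta"]

    def test_k_zero_gives_empty_and_large_k_gives_all(self):
        res = self._result({"a": 0.1, "b": 0.2})
        assert rank_top(res, "y", 0) == []
        assert len(rank_top(res, "y", 10)) == 2

    def test_unknown_output_rejected(self):
        res = self._result({"a": 0.1})
        with pytest.raises(es.ModelError):
            rank_top(res, "z", 1)
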
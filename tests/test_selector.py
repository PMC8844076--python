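import numpy as np
import pytest

import mmtfs
from mmtfs import (
    ConfigurationError,
    MMTFSError,
    SelectorConfig,
    WeightMatrix,
    fit,
    g1_norm,
    l21_norm,
    objective,
    one_hot,
    select_and_weight,
)


def loop_l21(W):
    return sum(np.sqrt(np.sum(row**2)) for row in W)


def loop_g1(W, block_map):
    total = 0.0
    for j in range(W.shape[1]):
        for _, (start, stop) in block_map:
            total += np.sqrt(np.sum(W[start:stop, j] ** 2))
    return total


def random_block_map(d, rng):
    cuts = np.sort(rng.choice(np.arange(1, d), size=rng.integers(1, min(4, d)), replace=False))
    edges = np.r_[0, cuts, d]
    return [(f"b{i}", (int(edges[i]), int(edges[i + 1]))) for i in range(len(edges) - 1)]


class TestNorms:
    def test_l21_simple_rows(self):
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == pytest.approx(5.0)
        assert l21_norm(np.eye(2)) == pytest.approx(2.0)
        assert l21_norm(np.zeros((4, 3))) == 0.0

    def test_g1_simple_blocks(self):
        one = [("all", (0, 2))]
        assert g1_norm(np.array([[3.0], [4.0]]), one) == pytest.approx(5.0)
        two = [("a", (0, 1)), ("b", (1, 2))]
        assert g1_norm(np.eye(2), two) == pytest.approx(2.0)  # unit block per class

    def test_g1_reduces_to_frobenius_for_single_block_and_class(self, rng):
        W = rng.normal(size=(6, 1))
        assert g1_norm(W, [("all", (0, 6))]) == pytest.approx(np.linalg.norm(W))

    def test_loop_oracle_agreement(self, rng):
        for _ in range(20):
            W = rng.normal(size=(10, 3))
            bm = random_block_map(10, rng)
            assert l21_norm(W) == pytest.approx(loop_l21(W), abs=1e-12)
            assert g1_norm(W, bm) == pytest.approx(loop_g1(W, bm), abs=1e-12)

    def test_l1_dominates_both_norms(self, rng):
        W = rng.normal(size=(8, 3))
        bm = random_block_map(8, rng)
        l1 = np.abs(W).sum()
        assert l21_norm(W) <= l1 + 1e-12
        assert g1_norm(W, bm) <= l1 + 1e-12
        # equality when each row / block-column holds a single nonzero
        single = np.zeros((4, 2))
        single[0, 1], single[2, 0] = 3.0, -2.0
        assert l21_norm(single) == pytest.approx(5.0)
        assert g1_norm(single, [("a", (0, 1)), ("b", (1, 4))]) == pytest.approx(5.0)

    def test_block_map_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            g1_norm(np.zeros((4, 2)), [("a", (0, 3))])


class TestObjective:
    def test_zero_weights_give_half_label_mass(self, rng):
        X = rng.normal(size=(5, 12))
        Y = one_hot(rng.choice(["a", "b"], size=12), ["a", "b"])
        cfg = SelectorConfig(gamma1=1.0, gamma2=1.0)
        val = objective(np.zeros((5, 2)), X, Y, cfg, [("all", (0, 5))])
        assert val == pytest.approx(12 / 2)

    def test_least_squares_residual_matches_normal_equations(self, rng):
        X = rng.normal(size=(6, 40))
        Y = one_hot(rng.choice(["a", "b"], size=40), ["a", "b"])
        W_ls = np.linalg.solve(X @ X.T, X @ Y.T)
        cfg = SelectorConfig(gamma1=0.0, gamma2=0.0)
        resid = 0.5 * np.sum((W_ls.T @ X - Y) ** 2)
        assert objective(W_ls, X, Y, cfg, [("all", (0, 6))]) == pytest.approx(resid, abs=1e-8)

    def test_penalties_only_increase(self, rng):
        X = rng.normal(size=(4, 10))
        Y = one_hot(rng.choice(["a", "b"], size=10), ["a", "b"])
        W = rng.normal(size=(4, 2))
        bm = [("all", (0, 4))]
        base = objective(W, X, Y, SelectorConfig(gamma1=0.0, gamma2=0.0), bm)
        assert objective(W, X, Y, SelectorConfig(gamma1=0.5, gamma2=0.5), bm) >= base

    def test_dimension_mismatch_named(self, rng):
        X = rng.normal(size=(4, 10))
        Y = one_hot(rng.choice(["a", "b"], size=10), ["a", "b"])
        with pytest.raises(ConfigurationError, match="W"):
            objective(np.zeros((5, 2)), X, Y, SelectorConfig(), [("all", (0, 5))])
        with pytest.raises(ConfigurationError, match="Y"):
            objective(np.zeros((4, 3)), X, Y, SelectorConfig(), [("all", (0, 4))])


class TestFit:
    def _problem(self, rng, d=6, n=40, c=2):
        X = rng.normal(size=(d, n))
        y = rng.choice([f"c{k}" for k in range(c)], size=n)
        Y = one_hot(y, sorted(set(y)))
        return X, Y, [("a", (0, d // 2)), ("b", (d // 2, d))]

    def test_huge_gamma2_shrinks_to_zero(self, rng):
        X, Y, bm = self._problem(rng)
        wm, _, _ = fit(X, Y, bm, SelectorConfig(gamma1=0.0, gamma2=1e6))
        assert np.linalg.norm(wm.W) < 1e-4

    def test_gamma_zero_matches_normal_equations(self, rng):
        X = rng.normal(size=(10, 40))
        Y = one_hot(rng.choice(["a", "b"], size=40), ["a", "b"])
        cfg = SelectorConfig(gamma1=0.0, gamma2=0.0, fit_intercept=False)
        wm, trace, conv = fit(X, Y, [("all", (0, 10))], cfg)
        W_ls = np.linalg.solve(X @ X.T, X @ Y.T)
        assert conv
        assert np.allclose(wm.W, W_ls, atol=1e-6)

    def test_trace_monotone_nonincreasing(self, rng):
        X, Y, bm = self._problem(rng, d=8, n=30)
        _, trace, _ = fit(X, Y, bm, SelectorConfig(gamma1=0.7, gamma2=0.4))
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(len(trace) - 1))

    def test_deterministic_and_sample_order_invariant(self, rng):
        X, Y, bm = self._problem(rng)
        cfg = SelectorConfig(gamma1=0.3, gamma2=0.3)
        w1, t1, _ = fit(X, Y, bm, cfg)
        w2, t2, _ = fit(X, Y, bm, cfg)
        assert np.array_equal(w1.W, w2.W) and t1 == t2
        perm = rng.permutation(X.shape[1])
        w3, _, _ = fit(X[:, perm], Y[:, perm], bm, cfg)
        assert np.allclose(w3.W, w1.W, atol=1e-10)

    def test_returned_point_is_local_minimum(self, rng):
        X = rng.normal(size=(4, 12))
        Y = one_hot(rng.choice(["a", "b"], size=12), ["a", "b"])
        bm = [("a", (0, 2)), ("b", (2, 4))]
        cfg = SelectorConfig(gamma1=0.5, gamma2=0.5, tol=1e-12, max_iter=2000,
                             fit_intercept=False)
        wm, _, _ = fit(X, Y, bm, cfg)
        f0 = objective(wm.W, X, Y, cfg, bm)
        for _ in range(1000):
            delta = rng.normal(size=wm.W.shape)
            delta *= 1e-3 / np.linalg.norm(delta)
            assert objective(wm.W + delta, X, Y, cfg, bm) >= f0 - 1e-9

    def test_row_sparsity_monotone_in_gamma2(self, rng):
        X, Y, bm = self._problem(rng, d=10, n=50)
        counts = []
        for g2 in (0.01, 0.1, 1.0, 10.0):
            wm, _, _ = fit(X, Y, bm, SelectorConfig(gamma1=0.0, gamma2=g2))
            counts.append(int(np.sum(np.sqrt((wm.W**2).sum(axis=1)) > 1e-6)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_g1_keeps_both_modalities_alive(self):
        """With signal in both blocks, gamma1 > 0 leaves importance in both."""
        ds, _ = mmtfs.generate_cohort(mmtfs.CohortSpec(
            n_per_class=40, d_imaging=10, d_snp=30, k_informative_imaging=3,
            k_informative_snp=3, effect_size=1.2, snp_effect=0.3, seed=6))
        dsn, _ = mmtfs.normalize_dataset(ds)
        Y = one_hot(dsn.y, dsn.class_order)
        wm, _, _ = fit(dsn.X.T, Y, dsn.modality_blocks, SelectorConfig(gamma1=5.0, gamma2=5.0))
        imp = wm.importance
        assert imp[:10].sum() > 0 and imp[10:].sum() > 0

    def test_nonfinite_input_rejected(self, rng):
        X, Y, bm = self._problem(rng)
        X[0, 0] = np.nan
        with pytest.raises(MMTFSError, match="iteration"):
            fit(X, Y, bm, SelectorConfig())


class TestSelectAndWeight:
    def _wm(self, importance_rows, block_map):
        W = np.column_stack([np.asarray(importance_rows), np.zeros(len(importance_rows))])
        return WeightMatrix(W, block_map)

    def test_stated_arithmetic(self):
        wm = self._wm([0.5, 0.1, 0.4], [("only", (0, 3))])
        res, out = select_and_weight(wm, np.ones((2, 3)), 2)
        assert res.selected["only"].tolist() == [0, 2]
        assert np.allclose(res.normalized_weights["only"], [5 / 9, 4 / 9])
        assert np.allclose(out, [[5 / 9, 4 / 9], [5 / 9, 4 / 9]])

    def test_k_equal_to_width_keeps_all(self, rng):
        wm = self._wm(rng.uniform(0.1, 1, size=5), [("only", (0, 5))])
        res, out = select_and_weight(wm, rng.normal(size=(4, 5)), 5)
        assert res.selected["only"].tolist() == [0, 1, 2, 3, 4]
        assert res.normalized_weights["only"].sum() == pytest.approx(1.0)

    def test_ties_break_to_lower_index(self):
        wm = self._wm([0.3, 0.3, 0.3, 0.1], [("only", (0, 4))])
        res, _ = select_and_weight(wm, np.ones((2, 4)), 2)
        assert res.selected["only"].tolist() == [0, 1]

    def test_all_zero_block_is_error(self):
        wm = self._wm([0.0, 0.0, 1.0], [("dead", (0, 2)), ("ok", (2, 3))])
        with pytest.raises(MMTFSError, match="dead"):
            select_and_weight(wm, np.ones((2, 3)), 1)

    def test_max_scheme_normalizes_to_unit_max(self):
        wm = self._wm([0.5, 0.1, 0.4], [("only", (0, 3))])
        res, _ = select_and_weight(wm, np.ones((2, 3)), 2, weight_norm="max")
        assert np.allclose(res.normalized_weights["only"], [1.0, 0.8])
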
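"""Similarity network fusion: kernel, normalization, sparsification, fusion."""

import numpy as np
import pytest
from scipy import stats

from modenet.core import ConnectivityMode, upper_values
from modenet.fusion import (
    FusionConfig,
    affinity_kernel,
    hyperparameter_sensitivity,
    knn_sparsify,
    leave_one_out_robustness,
    snf_fuse,
    snf_normalize,
)


def _sym(m):
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return ConnectivityMode(m)


def _kernel_oracle(matrix, mu, k, floor=1e-12):
    """Naive loop-by-loop evaluation of the affinity kernel definition."""
    x = matrix.copy()
    np.fill_diagonal(x, 0.0)
    n = x.shape[0]
    rho = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            keep = [c for c in range(n) if c not in (i, j)]
            rho[i, j] = np.linalg.norm(x[i, keep] - x[j, keep])
    knn_mean = np.empty(n)
    for i in range(n):
        others = np.sort([rho[i, j] for j in range(n) if j != i])
        knn_mean[i] = np.mean(others[:k])
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            eps = (knn_mean[i] + knn_mean[j] + rho[i, j]) / 3
            w[i, j] = np.exp(-rho[i, j] ** 2 / (mu * max(eps, floor)))
    return w


class TestAffinityKernel:
    def test_identical_rows_give_unit_affinity(self):
        m = np.array(
            [
                [0.0, 0.5, 0.2, 0.1],
                [0.5, 0.0, 0.2, 0.1],
                [0.2, 0.2, 0.0, 0.9],
                [0.1, 0.1, 0.9, 0.0],
            ]
        )
        # rows 0 and 1 identical once self-entries are removed
        w = affinity_kernel(ConnectivityMode(m), FusionConfig(K=2))
        assert w[0, 1] == pytest.approx(1.0)

    def test_all_identical_regions_floored_no_nan(self):
        m = np.full((6, 6), 0.4)
        np.fill_diagonal(m, 0)
        w = affinity_kernel(ConnectivityMode(m), FusionConfig(K=2))
        assert np.isfinite(w).all()
        np.testing.assert_allclose(w, 1.0)

    def test_matches_loop_oracle_on_hand_matrix(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        cfg = FusionConfig(mu=0.5, K=2)
        w = affinity_kernel(ConnectivityMode(m), cfg)
        expected = _kernel_oracle(m, 0.5, 2)
        np.testing.assert_allclose(w, expected, atol=1e-10)


class TestSnfNormalize:
    def test_row_sums_exactly_one_and_diag_half(self):
        rng = np.random.default_rng(2)
        w = np.abs(rng.standard_normal((7, 7)))
        p = snf_normalize(w)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(p), 0.5)

    def test_matrix_of_ones(self):
        p = snf_normalize(np.ones((3, 3)))
        assert p[0, 1] == pytest.approx(0.25)
        assert p[0, 0] == pytest.approx(0.5)

    def test_zero_row_rejected_naming_region(self):
        w = np.ones((3, 3))
        w[1, :] = 0.0
        w[:, 1] = 0.0
        with pytest.raises(ValueError, match="1"):
            snf_normalize(w)


class TestKnnSparsify:
    def test_k_equals_n_minus_one_is_row_normalized(self):
        rng = np.random.default_rng(3)
        w = np.abs(rng.standard_normal((5, 5)))
        s = knn_sparsify(w, 4)
        off = w.copy()
        np.fill_diagonal(off, 0)
        np.testing.assert_allclose(s, off / off.sum(axis=1, keepdims=True), atol=1e-12)

    def test_k_one_single_entry_per_row(self):
        rng = np.random.default_rng(4)
        w = np.abs(rng.standard_normal((6, 6)))
        s = knn_sparsify(w, 1)
        assert np.all((s > 0).sum(axis=1) == 1)
        np.testing.assert_allclose(s.sum(axis=1), 1.0)

    def test_hand_case_k2(self):
        w = np.array(
            [
                [9.0, 4.0, 2.0, 1.0],
                [4.0, 9.0, 3.0, 5.0],
                [2.0, 3.0, 9.0, 6.0],
                [1.0, 5.0, 6.0, 9.0],
            ]
        )
        s = knn_sparsify(w, 2)
        np.testing.assert_allclose(s[0], [0, 4 / 6, 2 / 6, 0])
        np.testing.assert_allclose(s[1], [4 / 9, 0, 0, 5 / 9])
        np.testing.assert_allclose(s[3], [0, 5 / 11, 6 / 11, 0])


class TestSnfFuse:
    def test_identical_modes_consistency(self, small_suite):
        # the update is a smoothing diffusion, so even identical inputs are
        # not a literal fixed point; the consistency limit that does hold:
        # the result is independent of how many copies are fused, and stays
        # positively rank-aligned with the input affinity
        m = small_suite["modes"][0]
        fused3 = snf_fuse(
            [ConnectivityMode(m.matrix.copy(), mode_name=f"c{i}") for i in range(3)],
            FusionConfig(),
        )
        fused5 = snf_fuse(
            [ConnectivityMode(m.matrix.copy(), mode_name=f"c{i}") for i in range(5)],
            FusionConfig(),
        )
        np.testing.assert_allclose(fused3.matrix, fused5.matrix, atol=1e-10)
        w = affinity_kernel(m, FusionConfig())
        r = stats.spearmanr(upper_values(fused3.matrix), upper_values(w)).statistic
        assert r > 0.5

    def test_single_fusion_iteration_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        modes = [_sym(rng.standard_normal((5, 5))) for _ in range(2)]
        cfg = FusionConfig(mu=0.5, K=2, n_iterations=1)
        fused = snf_fuse(modes, cfg)
        # oracle: the update P(v) <- S(v) @ mean_{k!=v} P(k) @ S(v).T computed
        # with explicit loops, then renormalized, symmetrized, and averaged
        ws = [_kernel_oracle(m.matrix, 0.5, 2) for m in modes]
        ps = [snf_normalize(w) for w in ws]
        ss = [knn_sparsify(w, 2) for w in ws]
        new_ps = []
        for v in range(2):
            other = ps[1 - v]
            pv = np.zeros((5, 5))
            for i in range(5):
                for j in range(5):
                    pv[i, j] = sum(
                        ss[v][i, a] * other[a, b] * ss[v][j, b]
                        for a in range(5)
                        for b in range(5)
                    )
            pv = snf_normalize(pv)
            pv = (pv + pv.T) / 2
            new_ps.append(pv)
        expected = np.mean(new_ps, axis=0)
        expected = (expected + expected.T) / 2
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(fused.matrix, expected, atol=1e-10)

    def test_planted_block_structure_amplified(self):
        margins_inputs, margins_fused = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 10)
            block = np.where(labels[:, None] == labels[None, :], 0.6, -0.2)
            modes = [
                _sym(block + rng.normal(0, 0.5, (20, 20))) for _ in range(2)
            ]
            within = labels[:, None] == labels[None, :]
            iu = np.triu_indices(20, k=1)
            wmask = within[iu]

            def margin(mat):
                v = mat[iu]
                order = stats.rankdata(v)
                return order[wmask].mean() - order[~wmask].mean()

            fused = snf_fuse(modes, FusionConfig(K=4))
            margins_inputs.append(max(margin(m.matrix) for m in modes))
            margins_fused.append(margin(fused.matrix))
        assert np.mean(margins_fused) > np.mean(margins_inputs)

    def test_output_nonnegative_symmetric(self, small_suite):
        fused = snf_fuse(small_suite["modes"], FusionConfig())
        assert np.all(fused.matrix >= 0)
        np.testing.assert_allclose(fused.matrix, fused.matrix.T, atol=1e-12)
        assert np.all(np.diag(fused.matrix) == 0)

    def test_row_stochastic_after_every_normalization(self, small_suite):
        # replay the iteration with the library primitives, asserting the
        # invariant at each step
        modes = small_suite["modes"]
        cfg = FusionConfig()
        k = cfg.resolve_k(modes[0].n_regions)
        ws = [affinity_kernel(m, cfg) for m in modes]
        ps = [snf_normalize(w) for w in ws]
        ss = [knn_sparsify(w, k) for w in ws]
        for p in ps:
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        m = len(modes)
        for _ in range(5):
            total = np.sum(ps, axis=0)
            nxt = []
            for v in range(m):
                pv = ss[v] @ ((total - ps[v]) / (m - 1)) @ ss[v].T
                pv = snf_normalize(pv)
                np.testing.assert_allclose(pv.sum(axis=1), 1.0, atol=1e-10)
                assert np.all(pv >= 0)
                nxt.append((pv + pv.T) / 2)
            ps = nxt


class TestRobustness:
    def test_identical_modes_loo_near_one(self, small_suite):
        m = small_suite["modes"][0]
        copies = [ConnectivityMode(m.matrix.copy(), mode_name=f"c{i}") for i in range(4)]
        res = leave_one_out_robustness(copies, FusionConfig())
        assert len(res["per_mode"]) == 4
        assert res["min"] > 0.99

    def test_loo_requires_three_modes(self, small_suite):
        with pytest.raises(ValueError, match="3 modes"):
            leave_one_out_robustness(small_suite["modes"][:2], FusionConfig())

    def test_sensitivity_default_cell_is_one(self, small_suite):
        modes = small_suite["modes"]
        cfg = FusionConfig()
        k0 = cfg.resolve_k(modes[0].n_regions)
        grid = hyperparameter_sensitivity(modes, [k0, k0 + 2], [0.5, 0.8], cfg)
        assert grid.shape == (2, 2)
        assert grid[0, 0] == pytest.approx(1.0)
        assert np.all(grid > 0)

    def test_sensitivity_rejects_bad_k(self, small_suite):
        with pytest.raises(ValueError, match="out of"):
            hyperparameter_sensitivity(small_suite["modes"], [0], [0.5])
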
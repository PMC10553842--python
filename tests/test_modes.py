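"""Mode construction: normalization, similarity, composites, Fisher z."""

import numpy as np
import pytest
from scipy import stats

from modenet.core import ConnectivityMode, rank_edges, upper_values
from modenet.modes import (
    DonorExpressionSet,
    composite_pc1,
    differential_stability,
    feature_similarity,
    filter_by_stability,
    fisher_z,
    partial_feature_similarity,
    robust_sigmoid,
    timeseries_connectivity,
)


class TestRobustSigmoid:
    def test_formula_oracle_with_outlier(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
        scaled, rec = robust_sigmoid(x)
        med, iqr = np.median(x), np.percentile(x, 75) - np.percentile(x, 25)
        norm = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        expected = (norm - norm.min()) / (norm.max() - norm.min())
        np.testing.assert_allclose(scaled, expected, atol=1e-12)
        assert not rec.degenerate
        # the outlier is bounded, not runaway
        assert scaled[-1] == 1.0 and scaled[-2] < 1.0

    def test_monotone(self):
        x = np.array([-3.0, -1.0, 0.0, 2.0, 5.0])
        scaled, _ = robust_sigmoid(x)
        assert np.all(np.diff(scaled) > 0)

    def test_median_maps_to_sigmoid_midpoint(self):
        x = np.array([1.0, 2.0, 3.0])
        _, rec = robust_sigmoid(x)
        mid = 1 / (1 + np.exp(-(2.0 - rec.median) / (rec.iqr / 1.35)))
        assert mid == pytest.approx(0.5)

    def test_degenerate_all_equal(self):
        scaled, rec = robust_sigmoid(np.full(5, 2.0))
        assert rec.degenerate
        np.testing.assert_array_equal(scaled, 0.5)


def test_zscore_features_columnwise():
    from modenet.modes import zscore_features

    rng = np.random.default_rng(0)
    f = rng.standard_normal((20, 5)) * [1, 2, 3, 4, 5] + [10, 0, -3, 1, 2]
    z = zscore_features(f)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)
    # z-scoring is columnwise, so it changes interregional similarity only
    # through the per-feature rescaling, never the region ordering
    assert z.shape == f.shape


class TestDifferentialStability:
    def test_identical_profiles(self):
        b = np.random.default_rng(0).standard_normal((10, 4))
        ds = differential_stability(DonorExpressionSet([b, b.copy()]))
        np.testing.assert_allclose(ds, 1.0)

    def test_reversed_profiles(self):
        b = np.arange(20, dtype=float).reshape(10, 2)
        ds = differential_stability(DonorExpressionSet([b, -b]))
        np.testing.assert_allclose(ds, -1.0)

    def test_three_donors_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(5)
        donors = [rng.standard_normal((8, 3)) for _ in range(3)]
        ds = differential_stability(DonorExpressionSet(donors))
        for p in range(3):
            expected = np.mean(
                [
                    stats.spearmanr(donors[i][:, p], donors[j][:, p]).statistic
                    for i in range(3)
                    for j in range(i + 1, 3)
                ]
            )
            assert ds[p] == pytest.approx(expected)

    def test_invariant_under_monotone_per_donor_transform(self):
        rng = np.random.default_rng(6)
        donors = [rng.standard_normal((9, 4)) for _ in range(3)]
        base = differential_stability(DonorExpressionSet(donors))
        warped = [np.exp(donors[0]), donors[1] ** 3 + 2, 5 * donors[2] - 1]
        np.testing.assert_allclose(
            differential_stability(DonorExpressionSet(warped)), base, atol=1e-12
        )

    def test_requires_two_donors(self):
        with pytest.raises(ValueError, match="2 donors"):
            differential_stability(DonorExpressionSet([np.zeros((5, 2))]))

    @pytest.mark.parametrize(
        "threshold,expected", [(0.1, ["f2"]), (-1.0, ["f0", "f1", "f2"]), (1.0, [])]
    )
    def test_stability_filter_strict_inequality(self, threshold, expected, monkeypatch):
        dset = DonorExpressionSet(
            [np.zeros((4, 3)), np.zeros((4, 3))], feature_ids=["f0", "f1", "f2"]
        )
        monkeypatch.setattr(
            "modenet.modes.differential_stability",
            lambda _: np.array([0.05, 0.1, 0.5]),
        )
        kept, _ = filter_by_stability(dset, threshold)
        assert kept == expected


class TestFeatureSimilarity:
    def test_identical_rows_r1(self):
        f = np.vstack([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4, 1, 3, 2]])
        r = feature_similarity(f).matrix
        assert r[0, 1] == pytest.approx(1.0)

    def test_orthogonal_centered_rows_r0(self):
        f = np.vstack([[1.0, -1, 1, -1], [1.0, 1, -1, -1], [0.5, 1, 1, 0.5]])
        r = feature_similarity(f).matrix
        assert r[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_corrcoef_oracle(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((3, 4))
        r = feature_similarity(f).matrix
        expected = np.corrcoef(f)
        np.testing.assert_allclose(r, expected, atol=1e-12)

    def test_zero_variance_row_gives_nan_edges(self):
        f = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        mode = feature_similarity(f)
        assert np.isnan(mode.matrix[0, 1])
        assert [0, 1] in mode.nan_edges.tolist()

    def test_region_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal((6, 8))
        perm = rng.permutation(6)
        base = feature_similarity(f).matrix
        permuted = feature_similarity(f[perm]).matrix
        np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)], atol=1e-12)


class TestPartialSimilarity:
    def test_all_regions_equal_mean_profile_degenerate(self):
        prof = np.arange(6.0)
        f = np.tile(prof, (4, 1))
        mode = partial_feature_similarity(f)
        assert np.isnan(upper_values(mode.matrix)).all()

    def test_mean_plus_independent_noise_near_zero(self):
        # with many regions the estimated mean profile approaches the truth
        # and the residual correlation -1/(n-1) vanishes
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = rng.standard_normal(800)
            f = prof + rng.standard_normal((40, 800))
            rs.append(partial_feature_similarity(f).matrix[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_precision_matrix_oracle(self):
        # partial corr of (x_i, x_j | mean profile) via the 3x3 precision matrix
        rng = np.random.default_rng(4)
        f = rng.standard_normal((4, 50))
        mode = partial_feature_similarity(f)
        mean_prof = f.mean(axis=0)
        for i in range(4):
            for j in range(i + 1, 4):
                c = np.corrcoef(np.vstack([f[i], f[j], mean_prof]))
                prec = np.linalg.inv(c)
                expected = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
                assert mode.matrix[i, j] == pytest.approx(expected, abs=1e-10)


class TestTimeseriesConnectivity:
    def test_copy_and_negation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        ts = np.vstack([x, x, -x])
        r = timeseries_connectivity(ts).matrix
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_ar1_pair_within_fisher_ci(self):
        rng = np.random.default_rng(8)
        t, rho = 10_000, 0.6
        innov = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=t).T
        x = np.zeros((2, t))
        for k in range(1, t):
            x[:, k] = 0.5 * x[:, k - 1] + innov[:, k]
        r = timeseries_connectivity(x).matrix[0, 1]
        # innovation correlation is preserved by identical AR(1) filtering;
        # Fisher CI half-width ~ 3.3/sqrt(T_eff) with T_eff < T
        z, zr = np.arctanh(r), np.arctanh(rho)
        assert abs(z - zr) < 0.06


class TestCompositePC1:
    def _mode(self, m):
        return ConnectivityMode((m + m.T) / 2)

    def test_six_copies_recovers_input(self):
        rng = np.random.default_rng(5)
        base = self._mode(rng.standard_normal((8, 8)))
        res = composite_pc1([base] * 6)
        r = np.corrcoef(upper_values(res.mode.matrix), upper_values(base.matrix))[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert res.var_explained[0] == pytest.approx(100.0)

    def test_anticorrelated_inputs_pc1_dominates_and_sign_stable(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((10, 10))
        mode_a = self._mode(a)
        mode_b = self._mode(-a + 0.1 * rng.standard_normal((10, 10)))
        res1 = composite_pc1([mode_a, mode_b])
        res2 = composite_pc1([mode_a, mode_b])
        assert res1.var_explained[0] > 50.0
        np.testing.assert_array_equal(res1.mode.matrix, res2.mode.matrix)

    def test_variance_ordering(self):
        rng = np.random.default_rng(7)
        ms = [self._mode(rng.standard_normal((9, 9))) for _ in range(4)]
        res = composite_pc1(ms)
        assert np.all(np.diff(res.var_explained) <= 1e-12)


class TestFisherZ:
    def test_zero_maps_to_zero_and_closed_form(self):
        m = np.array([[0.0, 0.5], [0.5, 0.0]])
        z = fisher_z(ConnectivityMode(m)).matrix
        assert z[0, 0] == 0.0
        assert z[0, 1] == pytest.approx(np.arctanh(0.5))
        assert z[0, 1] == pytest.approx(0.5493, abs=1e-4)

    def test_odd_symmetry(self):
        rng = np.random.default_rng(9)
        r = rng.uniform(-0.99, 0.99, size=(5, 5))
        r = (r + r.T) / 2
        zp = fisher_z(ConnectivityMode(r)).matrix
        zn = fisher_z(ConnectivityMode(-r)).matrix
        np.testing.assert_allclose(zn, -zp, atol=1e-12)

    def test_unit_correlation_clipped_finite(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        z = fisher_z(ConnectivityMode(m)).matrix
        assert np.isfinite(z).all()
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_out_of_range_rejected(self):
        m = np.array([[0.0, 1.1], [1.1, 0.0]])
        with pytest.raises(ValueError, match="> 1"):
            fisher_z(ConnectivityMode(m))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        r = rng.uniform(-0.9, 0.9, size=(8, 8))
        r = (r + r.T) / 2
        mode = ConnectivityMode(r)
        np.testing.assert_array_equal(
            rank_edges(mode).rank, rank_edges(fisher_z(mode)).rank
        )
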
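"""Per-gene statistics: channels, sketching, null moments, combination."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from spectrasvg import (
    benjamini_hochberg,
    cauchy_combine,
    channel_transform,
    evaluate_features,
    linear_trend_test,
    null_moments,
    per_scale_statistic,
    run_dataset,
    satterthwaite_pvalue,
    sparse_sketch,
    spatial_effect_size,
)
from spectrasvg import test_gene as single_gene_test
from spectrasvg.testing import ChannelVector, _sparse_moments


def _make_cv(values, n, channel="direct"):
    """ChannelVector from explicit (dense) values, bypassing the transform."""
    values = np.asarray(values, dtype=np.float64)
    idx = np.flatnonzero(values)
    mean, sd, kurt = _sparse_moments(values[idx], n)
    return ChannelVector(indices=idx, values=values[idx], n=n, mean=mean,
                         sd=sd, excess_kurtosis=kurt, channel=channel)


class TestChannelTransform:
    def test_binary_channel(self):
        cv = channel_transform([0, 0, 3, 0, 5], "binary")
        np.testing.assert_array_equal(cv.indices, [2, 4])
        np.testing.assert_array_equal(cv.values, [1, 1])
        assert cv.mean == pytest.approx(0.4)

    def test_rank_channel(self):
        cv = channel_transform([0, 0, 3, 0, 5], "rank")
        np.testing.assert_array_equal(cv.values, [1, 2])

    def test_rank_channel_average_ties(self):
        cv = channel_transform([0, 2, 2, 0, 7], "rank")
        np.testing.assert_array_equal(cv.values, [1.5, 1.5, 3])

    def test_direct_channel_keeps_counts(self):
        cv = channel_transform([0, 1, 0, 4], "direct")
        np.testing.assert_array_equal(cv.values, [1, 4])
        # population moments over all n entries including zeros
        y = np.array([0, 1, 0, 4.0])
        assert cv.sd == pytest.approx(y.std())
        mu4 = np.mean((y - y.mean()) ** 4)
        assert cv.excess_kurtosis == pytest.approx(mu4 / y.var() ** 2 - 3)

    def test_all_zero_gene_has_zero_sd(self):
        cv = channel_transform([0, 0, 0], "direct")
        assert cv.sd == 0.0 and cv.nnz == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            channel_transform([0, -1, 2], "direct")


class TestSparseSketch:
    def test_all_zero_gene_projects_to_zero(self, small_basis, small_moments, grid20):
        cv = channel_transform(np.zeros(len(grid20)), "direct")
        v = sparse_sketch(cv, small_basis, grid20, small_moments)
        np.testing.assert_array_equal(v, 0.0)

    def test_constant_gene_annihilated_by_centering(
        self, small_basis, small_moments, grid20
    ):
        cv = channel_transform(np.full(len(grid20), 3.0), "direct")
        v = sparse_sketch(cv, small_basis, grid20, small_moments)
        np.testing.assert_allclose(v, 0.0, atol=1e-10)

    def test_matches_dense_centered_product(self, small_basis, small_moments, grid20):
        rng = np.random.default_rng(1)
        y = np.where(rng.random(len(grid20)) < 0.2, rng.poisson(3, len(grid20)), 0)
        cv = channel_transform(y, "direct")
        v = sparse_sketch(cv, small_basis, grid20, small_moments)
        z = evaluate_features(small_basis, grid20)
        dense = (y - y.mean()) @ z
        np.testing.assert_allclose(v, dense, rtol=1e-10, atol=1e-12)

    def test_dimension_mismatch_rejected(self, small_basis, small_moments, grid20):
        cv = channel_transform([0, 1, 2], "direct")
        with pytest.raises(ValueError):
            sparse_sketch(cv, small_basis, grid20, small_moments)


class TestPerScaleStatistic:
    def test_zero_vector(self):
        t = per_scale_statistic(np.zeros(6), np.array([0, 0, 1, 1, 2, 2]))
        np.testing.assert_array_equal(t, 0.0)

    def test_single_entry(self):
        v = np.zeros(8)
        v[5] = 2.0
        t = per_scale_statistic(v, np.repeat([0, 1, 2, 3], 2))
        np.testing.assert_allclose(t, [0, 0, 4, 0])

    def test_sums_to_squared_norm(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=60)
        scales = np.repeat(np.arange(3), 20)
        assert per_scale_statistic(v, scales).sum() == pytest.approx(v @ v)


class TestNullMoments:
    def test_zero_kurtosis_reduces_to_gaussian_term(self, small_moments):
        cv = ChannelVector(np.array([0]), np.array([1.0]), n=400, mean=0.0,
                           sd=2.0, excess_kurtosis=0.0, channel="direct")
        e, v = null_moments(cv, small_moments, 400)
        np.testing.assert_allclose(
            v, 2 * 2.0**4 * 400**2 * small_moments.per_scale_frob_sq
        )
        np.testing.assert_allclose(
            e, 400 * 4.0 * small_moments.per_scale_sum_var
        )

    def test_homogeneity_in_sd(self, small_moments):
        kwargs = dict(indices=np.array([0]), values=np.array([1.0]), n=400,
                      mean=0.0, excess_kurtosis=1.5, channel="direct")
        e1, v1 = null_moments(ChannelVector(sd=1.0, **kwargs), small_moments, 400)
        e2, v2 = null_moments(ChannelVector(sd=2.0, **kwargs), small_moments, 400)
        np.testing.assert_allclose(e2, 4 * e1)  # E scales with sigma^2
        np.testing.assert_allclose(v2, 16 * v1)  # Var scales with sigma^4

    def test_degenerate_channel_rejected(self, small_moments):
        cv = ChannelVector(np.array([], dtype=int), np.array([]), n=400,
                           mean=0.0, sd=0.0, excess_kurtosis=0.0, channel="direct")
        with pytest.raises(ValueError):
            null_moments(cv, small_moments, 400)

    def test_matches_permutation_monte_carlo(self):
        # small instance: formulas vs 20,000 random reassignments of y
        from spectrasvg import build_bandwidth_ladder, compute_basis_moments, sample_basis

        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 10, size=(100, 2))
        basis = sample_basis(build_bandwidth_ladder(1.0, 5.0, 2), 20, seed=3)
        mom = compute_basis_moments(basis, pts)
        y = rng.poisson(0.7, 100).astype(float)
        cv = channel_transform(y, "direct")
        e, v = null_moments(cv, mom, 100)

        z = evaluate_features(basis, pts)
        zc = z - z.mean(axis=0)
        perms = np.array([rng.permutation(y) for _ in range(20_000)])
        proj = (perms - perms.mean(axis=1, keepdims=True)) @ zc
        t = np.stack(
            [np.sum(proj[:, basis.scale_of_feature == ell] ** 2, axis=1)
             for ell in range(2)], axis=1,
        )
        np.testing.assert_allclose(t.mean(axis=0), e, rtol=0.05)
        np.testing.assert_allclose(t.var(axis=0), v, rtol=0.20)

    def test_kurtosis_correction_direction(self, small_moments):
        # zero-inflated channel (kappa4 > 0): corrected Var >= Gaussian-only,
        # hence corrected p >= uncorrected p for the same statistic
        y = np.zeros(400)
        y[:20] = np.arange(1, 21)
        cv = channel_transform(y, "direct")
        assert cv.excess_kurtosis > 0
        e, v_corr = null_moments(cv, small_moments, 400)
        v_gauss = 2 * cv.sd**4 * 400**2 * small_moments.per_scale_frob_sq
        assert np.all(v_corr >= v_gauss)
        t = 1.5 * e
        p_corr = satterthwaite_pvalue(t, e, v_corr)
        p_gauss = satterthwaite_pvalue(t, e, v_gauss)
        assert np.all(p_corr >= p_gauss)


class TestSatterthwaite:
    def test_nu_one_case(self):
        # V = 2E^2 gives nu = 1, kappa = E, so p = P(chi2_1 > 1)
        assert satterthwaite_pvalue(1.0, 1.0, 2.0) == pytest.approx(
            stats.chi2.sf(1, 1), rel=1e-12
        )
        assert float(satterthwaite_pvalue(1.0, 1.0, 2.0)) == pytest.approx(
            0.3173, abs=1e-4
        )

    def test_zero_statistic_gives_one(self):
        assert satterthwaite_pvalue(0.0, 3.0, 1.0) == 1.0

    def test_large_nu_median_near_half(self):
        # T = E with nu large: chi2 median ~ nu, so p -> 0.5
        p = satterthwaite_pvalue(1.0, 1.0, 2e-4)  # nu = 10,000
        assert p == pytest.approx(0.5, abs=0.01)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError):
            satterthwaite_pvalue(1.0, 0.0, 1.0)


class TestLinearTrend:
    def test_orthogonal_gene_gives_p_one(self):
        # equal values on diagonally opposite corners: centered coordinate
        # sums over the support vanish in both columns, so X' y_c = 0
        pts = np.array([[0.0, 0], [0, 2], [2, 0], [2, 2], [1, 1]])
        y = np.array([1.0, 0, 0, 1.0, 0])
        p = linear_trend_test(_make_cv(y, 5), pts)
        assert p == pytest.approx(1.0)

    def test_gene_equal_to_coordinate_gives_t_n(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 10, size=(200, 2))
        y = pts[:, 0].copy()  # y_c lies in the column space of X
        cv = _make_cv(y, 200)
        p = linear_trend_test(cv, pts)
        # T = n = 200 on 2 df
        assert p == pytest.approx(stats.chi2.sf(200, 2), rel=1e-6)

    def test_collinear_coordinates_reduce_df(self):
        pts = np.column_stack([np.arange(10, dtype=float)] * 2)  # x == y
        y = np.zeros(10)
        y[::2] = [5, 1, 4, 2, 3]
        p = linear_trend_test(_make_cv(y, 10), pts)
        assert 0 < p <= 1

    def test_permutation_null_uniformity(self, grid20):
        rng = np.random.default_rng(9)
        y = rng.poisson(1.0, len(grid20)).astype(float)
        xc = grid20 - grid20.mean(axis=0)
        ginv = np.linalg.inv(xc.T @ xc)
        perms = np.array([rng.permutation(y) for _ in range(2000)])
        b = (perms - perms.mean(axis=1, keepdims=True)) @ xc
        t = np.einsum("gi,ij,gj->g", b, ginv, b) / y.var()
        p = stats.chi2.sf(t, 2)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestCauchyCombine:
    def test_median_components(self):
        assert cauchy_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_single_component_identity(self):
        assert cauchy_combine([0.05]) == pytest.approx(0.05, rel=1e-10)

    def test_symmetric_components_cancel(self):
        assert cauchy_combine([0.01, 0.5, 0.99]) == pytest.approx(0.5, abs=1e-12)

    def test_extreme_component_dominates(self):
        p = cauchy_combine([1e-12, 0.4, 0.6])
        assert p == pytest.approx(3e-12, rel=1e-3)  # ~ K * p_min for tiny p_min

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])

    def test_level_at_most_modestly_inflated(self):
        # under independent uniforms the combination is valid up to a small
        # margin: empirical level <= 1.5x nominal
        rng = np.random.default_rng(11)
        u = rng.random((10_000, 8))
        t = np.tan((0.5 - u) * np.pi).mean(axis=1)
        p = 0.5 - np.arctan(t) / np.pi
        for alpha in (0.01, 0.05):
            assert (p < alpha).mean() <= 1.5 * alpha


class TestEffectSizeAndBH:
    def test_effect_equal_observed_expected(self):
        assert spatial_effect_size([2.0, 3.0], [2.0, 3.0]) == 1.0

    def test_effect_takes_max_channel(self):
        assert spatial_effect_size([0.8, 2.5, 1.1], [1.0, 1.0, 1.0]) == 2.5

    def test_effect_zero_when_no_testable_channel(self):
        assert spatial_effect_size([0.0], [0.0]) == 0.0

    def test_bh_stepup_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_bh_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_bh_matches_textbook_stepup(self):
        rng = np.random.default_rng(2)
        p = rng.random(157)

        def textbook_bh(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            q = np.empty(m)
            prev = 1.0
            for rank_from_top, i in enumerate(order[::-1]):
                rank = m - rank_from_top
                prev = min(prev, pvals[i] * m / rank)
                q[i] = prev
            return q

        np.testing.assert_allclose(benjamini_hochberg(p), textbook_bh(p), rtol=1e-12)


class TestGeneLevel:
    def test_gradient_gene_strongly_significant(self, fitted20, grid20):
        y = np.round(5 * grid20[:, 0] / grid20[:, 0].max()).astype(float)
        res = single_gene_test(y, fitted20.basis_, grid20, fitted20.moments_)
        assert res.tested and res.combined_p < 1e-6
        assert res.effect_size > 1.0

    def test_presence_absence_structure_favors_binary_channel(self, fitted20, grid20):
        # expression detected mostly in the left half, nonzero magnitudes iid
        rng = np.random.default_rng(6)
        left = grid20[:, 0] < 10
        detect = rng.random(len(grid20)) < np.where(left, 0.8, 0.1)
        y = np.where(detect, rng.poisson(2.0, len(grid20)) + 1, 0).astype(float)
        res = single_gene_test(y, fitted20.basis_, grid20, fitted20.moments_)
        assert res.per_channel_p["binary"] < res.per_channel_p["rank"]
        assert res.combined_p < 1e-4

    def test_below_expression_filter_untested(self, fitted20, grid20):
        y = np.zeros(len(grid20))
        y[3] = 2.0
        res = single_gene_test(y, fitted20.basis_, grid20, fitted20.moments_, 5)
        assert not res.tested and np.isnan(res.combined_p)
        assert res.effect_size == 0.0

    def test_component_count_three_channels(self, fitted20, grid20):
        rng = np.random.default_rng(0)
        y = rng.poisson(1.0, len(grid20)).astype(float)
        res = single_gene_test(y, fitted20.basis_, grid20, fitted20.moments_)
        L = fitted20.basis_.n_scales
        assert res.component_p.shape == (3, L + 1)
        assert np.isfinite(res.component_p).sum() == 3 * (L + 1)


class TestRunDataset:
    def test_null_rejection_near_nominal(self, grid20):
        rng = np.random.default_rng(5)
        Y = sp.csr_matrix(rng.poisson(0.7, size=(100, len(grid20))))
        res = run_dataset(Y, grid20, n_features=120, n_scales=5, random_state=3)
        frac = (res.loc[res.tested, "p_combined"] < 0.05).mean()
        assert frac < 0.15  # ~5 of 100 expected; generous binomial slack

    def test_gene_order_irrelevant(self, fitted20, grid20):
        rng = np.random.default_rng(8)
        Y = sp.csr_matrix(rng.poisson(0.5, size=(30, len(grid20))))
        perm = rng.permutation(30)
        r1 = fitted20.transform(Y)
        r2 = fitted20.transform(Y[perm])
        np.testing.assert_allclose(
            r1["p_combined"].to_numpy()[perm], r2["p_combined"].to_numpy()
        )

    def test_duplicated_gene_rows_identical(self, fitted20, grid20):
        rng = np.random.default_rng(10)
        y = rng.poisson(1.0, len(grid20))
        Y = sp.csr_matrix(np.vstack([y, y]))
        res = fitted20.transform(Y)
        assert res.loc[0, "p_combined"] == res.loc[1, "p_combined"]
        assert res.loc[0, "effect_size"] == res.loc[1, "effect_size"]

    def test_parallel_equals_serial(self, grid20):
        rng = np.random.default_rng(13)
        Y = sp.csr_matrix(rng.poisson(0.5, size=(25, len(grid20))))
        from spectrasvg import SpatialVariabilityTest

        e1 = SpatialVariabilityTest(n_features=60, n_scales=3, random_state=1).fit(grid20)
        e2 = SpatialVariabilityTest(
            n_features=60, n_scales=3, random_state=1, n_jobs=2
        ).fit(grid20)
        r1, r2 = e1.transform(Y), e2.transform(Y)
        np.testing.assert_array_equal(
            r1["p_combined"].to_numpy(), r2["p_combined"].to_numpy()
        )

    def test_location_mismatch_rejected(self, fitted20):
        with pytest.raises(ValueError):
            fitted20.transform(sp.csr_matrix(np.ones((3, 7))))

    def test_sklearn_params_roundtrip(self):
        from spectrasvg import SpatialVariabilityTest

        est = SpatialVariabilityTest(n_features=64)
        params = est.get_params()
        assert params["n_features"] == 64
        est.set_params(n_scales=4)
        assert est.n_scales == 4
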
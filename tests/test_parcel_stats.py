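"""Parcel summaries, influence diagnostics and correlation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lagcvr import parcel_stats as ps
from lagcvr import synthetic_world as sw


def loo_cooks_oracle(x, y):
    """Leave-one-out refit oracle for Cook's distance on a bivariate OLS."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    fitted = X @ beta
    p = 2
    s2 = ((y - fitted) ** 2).sum() / (n - p)
    d = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        diff = X @ beta - X @ beta_i
        d[i] = (diff @ diff) / (p * s2)
    return d


class TestGmMedian:
    def test_constant_map(self):
        mask = np.ones((4, 4, 2), dtype=bool)
        assert ps.gm_median(np.full((4, 4, 2), 3.7), mask) == 3.7

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        mask = rng.random((6, 6, 3)) > 0.4
        vals = np.arange(np.prod(mask.shape), dtype=float).reshape(mask.shape)
        inside = np.sort(vals[mask])
        mid = len(inside) // 2
        oracle = inside[mid] if len(inside) % 2 else 0.5 * (inside[mid - 1] + inside[mid])
        assert ps.gm_median(vals, mask) == oracle

    def test_nan_voxels_excluded(self):
        mask = np.ones((3, 3, 1), dtype=bool)
        vals = np.arange(9, dtype=float).reshape(3, 3, 1)
        with_nan = vals.copy()
        with_nan[0, 0, 0] = np.nan
        assert ps.gm_median(with_nan, mask) == np.median(vals.ravel()[1:])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            ps.gm_median(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestParcelMeans:
    def test_piecewise_constant_map_recovered(self):
        atlas, _ = sw.make_atlas((12, 12, 6), 4)
        vals = np.zeros(atlas.shape)
        for lab in range(1, 9):
            vals[atlas == lab] = 10.0 * lab
        tab = ps.parcel_means(vals, atlas)
        np.testing.assert_allclose(tab["parcel_mean"], 10.0 * tab["parcel_id"])

    def test_hemisphere_split_gives_96_rows(self):
        atlas, _ = sw.make_atlas((24, 24, 12), 48)
        tab = ps.parcel_means(np.ones(atlas.shape), atlas)
        assert len(tab) == 96
        assert (tab["n_voxels"] >= 1).all()

    def test_voxel_order_invariance(self):
        rng = np.random.default_rng(1)
        atlas, _ = sw.make_atlas((12, 12, 6), 4)
        vals = rng.random(atlas.shape)
        tab = ps.parcel_means(vals, atlas)
        perm = rng.permutation(np.prod(atlas.shape))
        tab2 = ps.parcel_means(
            vals.ravel()[perm].reshape(atlas.shape),
            atlas.ravel()[perm].reshape(atlas.shape),
        )
        np.testing.assert_allclose(tab["parcel_mean"], tab2["parcel_mean"])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ps.parcel_means(np.zeros((4, 4, 2)), np.zeros((4, 4, 3), dtype=int))


class TestCooksDistance:
    def test_matches_loo_refit_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(12)
        y = 2 * x + rng.standard_normal(12)
        np.testing.assert_allclose(ps.cooks_distance(x, y), loo_cooks_oracle(x, y), atol=1e-10)

    def test_point_on_line_has_zero_influence(self):
        x = np.array([0.0, 1, 2, 3, 4, 2.0])
        y = 3.0 + 2.0 * x
        y_noisy = y + np.array([0.3, -0.3, 0.3, -0.3, 0.0, 0.0])
        d = ps.cooks_distance(x, y_noisy)
        assert d[5] < 0.05  # interior point near the consensus line

    def test_duplication_preserves_influence_ranks(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(8)
        y = x + rng.standard_normal(8) * 0.5
        d1 = ps.cooks_distance(x, y)
        d2 = ps.cooks_distance(np.r_[x, x], np.r_[y, y])
        assert list(np.argsort(d1)) == list(np.argsort(d2[:8]))
        assert (d2[:8] < d1).all()  # duplication dilutes each point's influence

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ps.cooks_distance(np.ones(6), np.arange(6.0))


class TestBetweenSubjects:
    def test_exact_linear_relationship(self):
        x = np.arange(9.0)
        res = ps.correlate_between_subjects(x, 2 * x + 1, remove_influential=False)
        assert res.full.r == pytest.approx(1.0)

    def test_null_type_one_error_calibrated(self):
        """Monte-Carlo null oracle: at n = 9 the Pearson test rejects at
        close to its nominal 5% rate."""
        rng = np.random.default_rng(4)
        n_sim = 10_000
        x = rng.standard_normal((n_sim, 9))
        y = rng.standard_normal((n_sim, 9))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt(7 / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=7)
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06
        # spot-check the vectorized oracle against the implementation
        res = ps.correlate_between_subjects(x[0], y[0], remove_influential=False)
        assert res.full.p == pytest.approx(p[0], rel=1e-8)

    def test_gross_outlier_flagged_by_4_over_n(self):
        x = np.arange(9.0)
        y = 2 * x.copy()
        y[8] = -30.0  # gross outlier in an otherwise perfect relationship
        res = ps.correlate_between_subjects(x, y, remove_influential=True)
        assert 8 in res.screened.removed_indices
        d = loo_cooks_oracle(x, y)
        assert np.argmax(d) == 8  # oracle confirms the max-influence point
        assert res.screened.r == pytest.approx(1.0)

    def test_single_pass_removal_is_idempotent(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12) * 0.4
        y[0] += 6.0
        first = ps.correlate_between_subjects(x, y, remove_influential=True)
        keep = np.setdiff1d(np.arange(12), first.screened.removed_indices)
        again = ps.correlate_between_subjects(
            x[keep], y[keep], remove_influential=False
        )
        assert again.full.r == pytest.approx(first.screened.r)


class TestSpatialCorrelation:
    def _tables(self, x, y):
        ids = np.arange(1, len(x) + 1)
        tx = pd.DataFrame({"parcel_id": ids, "parcel_mean": x, "n_voxels": 10})
        ty = pd.DataFrame({"parcel_id": ids, "parcel_mean": y, "n_voxels": 10})
        return tx, ty

    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(96)
        tx, ty = self._tables(x, np.exp(x))
        res = ps.correlate_spatial(tx, ty, remove_outlier_parcels=False)
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(96)
        y = 0.5 * x + rng.standard_normal(96)
        base = ps.correlate_spatial(*self._tables(x, y), remove_outlier_parcels=False)
        warped = ps.correlate_spatial(
            *self._tables(np.tanh(x), y**3), remove_outlier_parcels=False
        )
        assert warped.r == pytest.approx(base.r)

    def test_standardized_z_against_1_96_at_full_n(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(96)
        y = 0.25 * x + rng.standard_normal(96)
        res = ps.correlate_spatial(*self._tables(x, y), remove_outlier_parcels=False)
        assert res.critical_value == pytest.approx(1.96, abs=5e-3)
        assert res.fisher_z_std == pytest.approx(np.arctanh(res.r) * np.sqrt(93))
        assert res.significant == (abs(res.fisher_z_std) > res.critical_value)

    def test_mismatched_parcel_ids_rejected(self):
        tx, ty = self._tables(np.arange(12.0), np.arange(12.0))
        ty["parcel_id"] += 1
        with pytest.raises(ValueError, match="parcel ids"):
            ps.correlate_spatial(tx, ty)

    def test_planted_coupling_recovered(self):
        """Generator oracle: couple_fields plants a known Spearman level."""
        rng = np.random.default_rng(9)
        base = rng.standard_normal(96)
        rhos = []
        for seed in range(200):
            y = sw.couple_fields(base, 0.6, seed=seed)
            res = ps.correlate_spatial(
                *self._tables(base, y), remove_outlier_parcels=False
            )
            rhos.append(res.r)
        assert abs(np.mean(rhos) - 0.6) < 0.05


class TestCriticalValues:
    def test_alpha_05_gives_1_96(self):
        crit = ps.adjusted_critical_value(96, alpha=0.05)
        assert crit.z_crit == pytest.approx(1.959964, abs=1e-6)

    def test_removal_raises_required_rho(self):
        rhos = [ps.adjusted_critical_value(n).rho_crit for n in (96, 90, 80, 50, 20)]
        assert all(b > a for a, b in zip(rhos, rhos[1:]))

    def test_rho_threshold_matches_numeric_inversion(self):
        """Root-finding oracle: the |rho| threshold solves
        atanh(rho) * sqrt(n-3) = z_crit."""
        from scipy.optimize import brentq

        crit = ps.adjusted_critical_value(96, alpha=0.05)
        oracle = brentq(
            lambda r: np.arctanh(r) * np.sqrt(93) - crit.z_crit, 1e-6, 0.99
        )
        assert crit.rho_crit == pytest.approx(oracle, abs=1e-10)

    def test_fisher_z_round_trip(self):
        r = np.linspace(-0.999, 0.999, 41)
        np.testing.assert_allclose(np.tanh(np.arctanh(r)), r, atol=1e-12)


class TestFdr:
    def test_step_up_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(ps.fdr_adjust(p), 0.05)

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(ps.fdr_adjust(np.ones(6)), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=8)
        perm = rng.permutation(8)
        np.testing.assert_allclose(ps.fdr_adjust(p)[perm], ps.fdr_adjust(p[perm]))
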
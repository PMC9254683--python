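"""Design construction, voxelwise OLS and the two CVR mapping schemes."""

import numpy as np
import pytest

from lagcvr import capno, cvr_glm
from lagcvr import synthetic_world as sw
from conftest import fit_segment


def _simple_regset(n_volumes=120, tr=1.2, lag_limit=6.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = 40 + np.cumsum(rng.normal(0, 0.4, 600))
    pet = capno.PetCO2Series(np.arange(600, dtype=float), vals, 40.0)
    return capno.build_regressors(
        pet, tr_s=tr, n_volumes=n_volumes, lag_limit_s=lag_limit, lag_step_s=0.3,
        alignment_offset_s=100.0,
    )


class TestBuildDesign:
    def test_drift_columns_orthonormal(self):
        """Gram-matrix oracle: drift block is orthonormal and orthogonal to
        the intercept to machine precision."""
        d = cvr_glm.build_design(
            200, 1.2, drift_order=4, regressor_row=np.sin(np.arange(200.0))
        )
        drift = d.values[:, 1:5]
        gram = drift.T @ drift
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(drift.sum(axis=0), 0.0, atol=1e-10)

    def test_zero_motion_columns_dropped(self):
        motion = np.zeros((150, 6))
        d = cvr_glm.build_design(
            150, 1.2, drift_order=0, motion_table=motion,
            regressor_row=np.sin(np.arange(150.0)),
        )
        assert d.dropped_columns == [f"motion_{k}" for k in range(1, 7)]
        assert d.column_names == ["intercept", "petco2"]
        assert d.values.shape[1] == 2

    def test_duplicated_regressor_raises_rank_error(self):
        drift = cvr_glm.drift_basis(100, 1)[:, 0]
        with pytest.raises(ValueError, match="rank deficient"):
            cvr_glm.build_design(100, 1.2, drift_order=1, regressor_row=drift)

    def test_condition_number_reported(self):
        d = cvr_glm.build_design(
            100, 1.2, drift_order=2, regressor_row=np.cos(np.arange(100.0))
        )
        assert np.isfinite(d.condition_number) and d.condition_number >= 1.0

    def test_default_drift_order_rule(self):
        # one polynomial order per 150 s of scan, plus intercept elsewhere
        assert cvr_glm.default_drift_order(468.0) == 4
        assert cvr_glm.default_drift_order(120.0) == 1


class TestFitVoxel:
    def test_exact_fit_gives_r2_one(self):
        X = cvr_glm.build_design(
            80, 1.2, drift_order=1, regressor_row=np.sin(np.arange(80.0))
        )
        y = 3.0 * X.values[:, 0] + 0.5 * X.values[:, -1]
        betas, r2 = cvr_glm.fit_voxel(y, X)
        assert r2 == pytest.approx(1.0)
        assert betas[0] == pytest.approx(3.0)
        assert betas[-1] == pytest.approx(0.5)

    def test_orthogonal_series_gives_r2_zero(self):
        n = 64
        X = cvr_glm.build_design(
            n, 1.2, drift_order=0, regressor_row=np.sin(2 * np.pi * np.arange(n) / 8)
        )
        # a pure high-frequency cosine orthogonal to intercept and regressor
        y = np.cos(2 * np.pi * np.arange(n) * 16 / n)
        _, r2 = cvr_glm.fit_voxel(y, X)
        assert r2 == pytest.approx(0.0, abs=1e-10)

    def test_betas_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        betas, _ = cvr_glm.fit_voxel(y, X)
        oracle = np.linalg.pinv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(betas, oracle, atol=1e-10)

    def test_all_zero_series(self):
        X = cvr_glm.build_design(
            50, 1.2, drift_order=1, regressor_row=np.sin(np.arange(50.0))
        )
        betas, r2 = cvr_glm.fit_voxel(np.zeros(50), X)
        assert r2 == 0.0
        np.testing.assert_array_equal(betas, 0.0)


class TestCvrNoOpt:
    def test_single_voxel_forward_closure(self):
        """Mean 1000, amplitude 0.2 %BOLD/mmHg, lag 0, noiseless."""
        rs = _simple_regset()
        x = rs.row(0.0)
        bold = (1000.0 * (1 + 0.2 / 100.0 * x)).reshape(1, 1, 1, -1)
        mask = np.ones((1, 1, 1), dtype=bool)
        res = cvr_glm.cvr_no_opt(bold, mask, rs)
        assert res.cvr_amp[0, 0, 0] == pytest.approx(0.2, rel=1e-10)
        assert res.lag_s[0, 0, 0] == 0.0
        assert res.beta_mean[0, 0, 0] == pytest.approx(1000.0, rel=1e-10)

    def test_zero_mean_voxel_flagged_nan(self):
        rs = _simple_regset()
        n = rs.regressors.shape[1]
        bold = np.zeros((2, 1, 1, n))
        bold[1, 0, 0] = 1000.0 * (1 + 0.002 * rs.row(0.0))
        mask = np.ones((2, 1, 1), dtype=bool)
        res = cvr_glm.cvr_no_opt(bold, mask, rs)
        assert np.isnan(res.cvr_amp[0, 0, 0]) and res.boundary_flag[0, 0, 0]
        assert np.isfinite(res.cvr_amp[1, 0, 0])


class TestCvrLagOpt:
    def test_planted_on_grid_lag_recovered_exactly(self):
        rs = _simple_regset(n_volumes=200)
        true_lags = (6.0, -3.3, 0.0, 2.1)
        bold = np.stack(
            [1000.0 * (1 + 0.25 / 100.0 * rs.row(lag)) for lag in true_lags]
        ).reshape(len(true_lags), 1, 1, -1)
        mask = np.ones((len(true_lags), 1, 1), dtype=bool)
        res = cvr_glm.cvr_lag_opt(bold, mask, rs)
        np.testing.assert_allclose(res.lag_s[:, 0, 0], true_lags)
        np.testing.assert_allclose(res.cvr_amp[:, 0, 0], 0.25, rtol=1e-8)

    def test_planted_lag_zero_equals_no_opt(self):
        rs = _simple_regset(n_volumes=150)
        rng = np.random.default_rng(2)
        bold = 1000.0 * (
            1 + 0.2 / 100.0 * rs.row(0.0)
        ) + 0.0 * rng.standard_normal(150)
        bold = np.tile(bold, (3, 2, 1, 1))
        mask = np.ones((3, 2, 1), dtype=bool)
        opt = cvr_glm.cvr_lag_opt(bold, mask, rs)
        no = cvr_glm.cvr_no_opt(bold, mask, rs)
        np.testing.assert_allclose(opt.cvr_amp, no.cvr_amp, rtol=1e-9)
        assert np.all(opt.lag_s == 0.0)

    def test_argmax_dominance_on_noisy_data(self, noisy_subject):
        """Lag-Opt full-model R^2 >= No-Opt R^2 at every voxel, any dataset:
        the lag grid contains 0, so the maximum cannot be smaller."""
        gm = noisy_subject.gm_mask
        for label in noisy_subject.bold_segments:
            opt = fit_segment(noisy_subject, label, "Lag-Opt")
            no = fit_segment(noisy_subject, label, "No-Opt")
            assert np.all(opt.r_squared[gm] >= no.r_squared[gm] - 1e-12)

    def test_scale_equivariance(self):
        rs = _simple_regset(n_volumes=150)
        rng = np.random.default_rng(3)
        base = 1000.0 * (1 + 0.2 / 100.0 * rs.row(1.5)) + rng.normal(0, 5, 150)
        bold = base.reshape(1, 1, 1, -1)
        mask = np.ones((1, 1, 1), dtype=bool)
        r1 = cvr_glm.cvr_lag_opt(bold, mask, rs)
        r2 = cvr_glm.cvr_lag_opt(7.3 * bold, mask, rs)
        assert r1.cvr_amp[0, 0, 0] == pytest.approx(r2.cvr_amp[0, 0, 0], rel=1e-10)
        assert r1.lag_s[0, 0, 0] == r2.lag_s[0, 0, 0]

    def test_boundary_lag_flagged(self):
        rs = _simple_regset(n_volumes=150, lag_limit=3.0)
        bold = (1000.0 * (1 + 0.3 / 100.0 * rs.row(3.0))).reshape(1, 1, 1, -1)
        mask = np.ones((1, 1, 1), dtype=bool)
        res = cvr_glm.cvr_lag_opt(bold, mask, rs)
        assert res.lag_s[0, 0, 0] == 3.0
        assert res.boundary_flag[0, 0, 0]

    def test_empty_mask_rejected(self):
        rs = _simple_regset()
        with pytest.raises(ValueError, match="mask"):
            cvr_glm.cvr_lag_opt(
                np.zeros((2, 2, 2, rs.regressors.shape[1])),
                np.zeros((2, 2, 2), dtype=bool),
                rs,
            )


class TestFullGridClosure:
    def test_noiseless_recovery_to_numerical_precision(self, noiseless_bh_subject):
        """Forward and inverse share the regressor code path, so a noiseless
        subject is recovered exactly: amplitudes to float precision, lags
        on-grid with zero error."""
        sub = noiseless_bh_subject
        gm = sub.gm_mask
        res = fit_segment(sub, "BH+REST", "Lag-Opt")
        rel = np.abs(res.cvr_amp[gm] - sub.truth.cvr_amp_map[gm]) / sub.truth.cvr_amp_map[gm]
        assert np.nanmax(rel) < 1e-6
        assert np.array_equal(res.lag_s[gm], sub.truth.lag_map[gm])

    def test_rest_degrades_amplitude_recovery_vs_breathing_task(self, noisy_subject):
        """At matched noise, rest-only segments (small end-tidal variance)
        recover amplitude strictly worse than the breath-hold segment."""
        sub = noisy_subject
        gm = sub.gm_mask
        errs = {}
        for label in ("BH+REST", "REST"):
            res = fit_segment(sub, label, "Lag-Opt")
            errs[label] = np.nanmedian(
                np.abs(res.cvr_amp[gm] - sub.truth.cvr_amp_map[gm])
                / sub.truth.cvr_amp_map[gm]
            )
        assert errs["REST"] > errs["BH+REST"]
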
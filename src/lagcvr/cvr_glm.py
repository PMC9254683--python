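"""Voxelwise lagged-GLM cerebrovascular reactivity mapping.

Two schemes are produced from the same design:

* **No-Opt**: one ordinary least-squares fit per voxel with the unshifted
  (lag-0) end-tidal CO2 regressor; CVR is the CO2 beta scaled by the fitted
  mean, ``100 * beta_co2 / beta_mean`` in %BOLD/mmHg.
* **Lag-Opt**: the same model refit once per lag on a symmetric grid; per
  voxel the lag maximizing the full-model R^2 wins, and that model's scaled
  beta, lag and R^2 are reported.  Because the grid contains lag 0, the
  winning R^2 can never fall below the No-Opt R^2.

The design is ``[intercept | orthonormal polynomial drift | 6 demeaned motion
parameters | CO2 regressor]``; the CO2 column is *not* demeaned so that the
intercept estimates the voxel's baseline signal (the "fitted mean" used for
scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr, solve_triangular

logger = logging.getLogger("lagcvr")

__all__ = [
    "DesignMatrix",
    "CvrResult",
    "drift_basis",
    "build_design",
    "fit_voxel",
    "cvr_no_opt",
    "cvr_lag_opt",
    "default_drift_order",
]


def default_drift_order(duration_s, seconds_per_order=150.0):
    """Polynomial drift order: one order per ``seconds_per_order`` of scan."""
    return 1 + int(duration_s // seconds_per_order)


def drift_basis(n_volumes, order):
    """Orthonormal polynomial drift columns (order >= 1), each orthogonal to
    the constant column to machine precision.

    Built by QR-orthonormalizing the Vandermonde basis of a linear ramp over
    the scan, then dropping the constant; shared by the synthetic forward
    model so planted drift is exactly removable.
    """
    if order < 1:
        return np.empty((n_volumes, 0))
    t = np.linspace(-1.0, 1.0, n_volumes)
    V = np.vander(t, order + 1, increasing=True)  # [1, t, t^2, ...]
    Q, _ = np.linalg.qr(V)
    # fix sign so the linear column increases with time (determinism)
    for j in range(Q.shape[1]):
        if Q[-1, j] < 0:
            Q[:, j] = -Q[:, j]
    return Q[:, 1:]


@dataclass
class DesignMatrix:
    """Ordered design blocks with bookkeeping for QC."""

    values: np.ndarray
    column_names: list
    petco2_index: int
    condition_number: float
    dropped_columns: list = field(default_factory=list)

    @property
    def n_volumes(self):
        return self.values.shape[0]


def build_design(
    n_volumes,
    tr_s,
    drift_order=None,
    motion_table=None,
    regressor_row=None,
    seconds_per_order=150.0,
):
    """Assemble the GLM design for one segment.

    Motion columns are demeaned; all-zero (or constant) motion columns are
    dropped and logged rather than breaking the fit.  Raises on rank
    deficiency, naming the offending column.
    """
    if regressor_row is None:
        raise ValueError("regressor_row is required")
    regressor_row = np.asarray(regressor_row, dtype=np.float64)
    if len(regressor_row) != n_volumes:
        raise ValueError("regressor length does not match n_volumes")
    if drift_order is None:
        drift_order = default_drift_order(n_volumes * tr_s, seconds_per_order)

    cols = [np.ones(n_volumes)]
    names = ["intercept"]
    D = drift_basis(n_volumes, drift_order)
    for k in range(D.shape[1]):
        cols.append(D[:, k])
        names.append(f"drift_{k + 1}")

    dropped = []
    if motion_table is not None:
        motion = np.asarray(motion_table, dtype=np.float64)
        if motion.ndim != 2 or motion.shape[0] != n_volumes or motion.shape[1] != 6:
            raise ValueError("motion table must be n_volumes x 6")
        motion = motion - motion.mean(axis=0)
        for k in range(6):
            name = f"motion_{k + 1}"
            if np.allclose(motion[:, k], 0.0):
                dropped.append(name)
                logger.info("dropping constant motion column %s", name)
                continue
            cols.append(motion[:, k])
            names.append(name)

    cols.append(regressor_row)
    names.append("petco2")
    X = np.column_stack(cols)

    # rank check with column attribution
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = np.where(diag < max(X.shape) * np.finfo(float).eps * diag.max())[0]
    if len(bad):
        raise ValueError(f"design is rank deficient at column '{names[bad[0]]}'")
    cond = float(np.linalg.cond(X))
    return DesignMatrix(
        values=X,
        column_names=names,
        petco2_index=len(names) - 1,
        condition_number=cond,
        dropped_columns=dropped,
    )


def fit_voxel(y, X):
    """OLS fit of one series against a design (matrix or DesignMatrix).

    Returns ``(betas, r_squared)`` with R^2 about the mean.  An all-zero
    series yields zero betas and R^2 = 0 (logged); an exactly-fitted constant
    series yields R^2 = 1.
    """
    A = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if len(y) != A.shape[0]:
        raise ValueError("series length does not match design rows")
    if np.allclose(y, 0.0):
        logger.info("all-zero series: betas set to 0, R^2 to 0")
        return np.zeros(A.shape[1]), 0.0
    betas, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ betas
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-12 * float(y @ y) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return betas, float(np.clip(r2, 0.0, 1.0))


@dataclass
class CvrResult:
    """Voxelwise CVR amplitude / lag / fit maps for one scheme."""

    cvr_amp: np.ndarray  # %BOLD/mmHg
    lag_s: np.ndarray
    r_squared: np.ndarray
    boundary_flag: np.ndarray
    beta_mean: np.ndarray
    mask: np.ndarray
    scheme: str


def _mask_series(bold, mask):
    bold = np.asarray(bold, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if bold.shape[:-1] != mask.shape:
        raise ValueError("bold and mask grids differ")
    return bold[mask].T, mask  # [n_volumes, n_voxels]


def _fit_all(X, Y):
    """Vectorized OLS over all voxels via thin QR.

    Returns betas [p, n_vox], R^2 [n_vox] (about the mean).
    """
    Q, R = qr(X, mode="economic")
    C = Q.T @ Y
    betas = solve_triangular(R, C)
    ss_fit = np.einsum("ij,ij->j", C, C)
    ss_all = np.einsum("ij,ij->j", Y, Y)
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    ss_tot = ss_all - n * mean**2
    ss_res = np.maximum(ss_all - ss_fit, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot <= 0, np.where(ss_res <= 1e-12 * np.maximum(ss_all, 1e-300), 1.0, 0.0), r2)
    return betas, np.clip(r2, 0.0, 1.0)


def _scale_beta(b_co2, b_mean, eps):
    """CVR in %BOLD/mmHg with a guard on near-zero fitted means."""
    flagged = np.abs(b_mean) < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = 100.0 * b_co2 / b_mean
    amp[flagged] = np.nan
    return amp, flagged


def _nuisance_matrix(n_volumes, tr_s, drift_order, motion_table, seconds_per_order):
    """Intercept + drift + demeaned motion block (no CO2 column yet)."""
    if drift_order is None:
        drift_order = default_drift_order(n_volumes * tr_s, seconds_per_order)
    cols = [np.ones((n_volumes, 1)), drift_basis(n_volumes, drift_order)]
    if motion_table is not None:
        motion = np.asarray(motion_table, dtype=np.float64)
        if motion.ndim != 2 or motion.shape[0] != n_volumes or motion.shape[1] != 6:
            raise ValueError("motion table must be n_volumes x 6")
        motion = motion - motion.mean(axis=0)
        keep = ~np.all(np.isclose(motion, 0.0), axis=0)
        if not keep.all():
            logger.info("dropping %d constant motion columns", int((~keep).sum()))
        cols.append(motion[:, keep])
    return np.column_stack(cols)


def cvr_no_opt(
    bold,
    mask,
    regressor_set,
    motion_table=None,
    drift_order=None,
    tr_s=None,
    seconds_per_order=150.0,
    beta_mean_eps_factor=1e-6,
):
    """CVR mapping with the unshifted (lag-0) regressor only."""
    Y, mask = _mask_series(bold, mask)
    tr = tr_s if tr_s is not None else regressor_set.tr_s
    N = _nuisance_matrix(Y.shape[0], tr, drift_order, motion_table, seconds_per_order)
    X = np.column_stack([N, regressor_set.regressors[regressor_set.lag0_index]])
    betas, r2 = _fit_all(X, Y)
    eps = beta_mean_eps_factor * float(np.abs(Y).mean())
    amp, flagged = _scale_beta(betas[-1], betas[0], eps)

    out = _empty_maps(mask)
    out["cvr_amp"][mask] = amp
    out["r_squared"][mask] = r2
    out["beta_mean"][mask] = betas[0]
    out["boundary_flag"][mask] = flagged
    return CvrResult(
        cvr_amp=out["cvr_amp"],
        lag_s=out["lag_s"],
        r_squared=out["r_squared"],
        boundary_flag=out["boundary_flag"],
        beta_mean=out["beta_mean"],
        mask=mask,
        scheme="no_opt",
    )


def cvr_lag_opt(
    bold,
    mask,
    regressor_set,
    motion_table=None,
    drift_order=None,
    tr_s=None,
    seconds_per_order=150.0,
    beta_mean_eps_factor=1e-6,
    censor_boundary=False,
):
    """CVR mapping with per-voxel hemodynamic-lag optimization.

    One GLM per lag per voxel; the lag with the largest full-model R^2 wins.
    Ties break deterministically toward the smallest ``|lag|``, negative
    before positive.  Voxels whose winning lag sits at the grid edge are
    flagged (and NaN-ed only when ``censor_boundary``); results are
    independent of voxel iteration order by construction.
    """
    Y, mask = _mask_series(bold, mask)
    tr = tr_s if tr_s is not None else regressor_set.tr_s
    N = _nuisance_matrix(Y.shape[0], tr, drift_order, motion_table, seconds_per_order)

    lags = regressor_set.lags_s
    order = sorted(range(len(lags)), key=lambda i: (abs(lags[i]), lags[i] > 0))
    n_vox = Y.shape[1]
    best_r2 = np.full(n_vox, -np.inf)
    best_lag = np.zeros(n_vox)
    best_b0 = np.zeros(n_vox)
    best_bco2 = np.zeros(n_vox)
    X = np.empty((Y.shape[0], N.shape[1] + 1))
    X[:, :-1] = N
    for i in order:
        X[:, -1] = regressor_set.regressors[i]
        betas, r2 = _fit_all(X, Y)
        win = r2 > best_r2
        best_r2[win] = r2[win]
        best_lag[win] = lags[i]
        best_b0[win] = betas[0][win]
        best_bco2[win] = betas[-1][win]

    eps = beta_mean_eps_factor * float(np.abs(Y).mean())
    amp, flagged_mean = _scale_beta(best_bco2, best_b0, eps)
    at_edge = np.isclose(np.abs(best_lag), np.abs(lags).max())
    if censor_boundary:
        amp[at_edge] = np.nan

    out = _empty_maps(mask)
    out["cvr_amp"][mask] = amp
    out["lag_s"][mask] = best_lag
    out["r_squared"][mask] = best_r2
    out["beta_mean"][mask] = best_b0
    out["boundary_flag"][mask] = at_edge | flagged_mean
    return CvrResult(
        cvr_amp=out["cvr_amp"],
        lag_s=out["lag_s"],
        r_squared=out["r_squared"],
        boundary_flag=out["boundary_flag"],
        beta_mean=out["beta_mean"],
        mask=mask,
        scheme="lag_opt",
    )


def _empty_maps(mask):
    shape = mask.shape
    return {
        "cvr_amp": np.full(shape, np.nan),
        "lag_s": np.zeros(shape),
        "r_squared": np.zeros(shape),
        "beta_mean": np.zeros(shape),
        "boundary_flag": np.zeros(shape, dtype=bool),
    }
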
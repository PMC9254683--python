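"""Parcel summaries and correlation statistics with influence diagnostics.

Two families of correlations mirror the two levels of the analysis:

* **between subjects** — Pearson correlation of per-subject gray-matter
  median CVR against median CBF, reported with and without influential
  subjects (Cook's distance > 4/n on the bivariate fit) removed in a single
  screening pass;
* **within subject, spatial** — Spearman rank correlation of 96 parcel means
  (CVR or a resting-state metric vs CBF), with outlier parcels screened by
  Cook's distance on the rank-rank regression, Fisher Z transformed and
  tested against a two-tailed normal critical value standardized by
  ``sqrt(n_used - 3)``.  Removing parcels lowers ``n_used`` and therefore
  raises the |rho| needed for significance; the adjusted threshold is
  reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("lagcvr")

__all__ = [
    "CorrelationResult",
    "CriticalValue",
    "gm_median",
    "parcel_means",
    "cooks_distance",
    "correlate_between_subjects",
    "correlate_spatial",
    "adjusted_critical_value",
    "fdr_adjust",
]


def gm_median(map_3d, gm_mask):
    """Median over finite in-mask voxels; NaNs excluded with a log line."""
    map_3d = np.asarray(map_3d, dtype=np.float64)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if map_3d.shape != gm_mask.shape:
        raise ValueError("map and mask grids differ")
    if not gm_mask.any():
        raise ValueError("empty gray-matter mask")
    vals = map_3d[gm_mask]
    finite = np.isfinite(vals)
    n_nan = int((~finite).sum())
    if n_nan:
        logger.info("gm_median: excluding %d non-finite voxels", n_nan)
    if not finite.any():
        raise ValueError("all in-mask voxels are non-finite")
    return float(np.median(vals[finite]))


def parcel_means(map_3d, atlas, map_kind=None):
    """Arithmetic mean of finite voxels per atlas label.

    Returns a DataFrame with columns ``parcel_id``, ``parcel_mean`` and
    ``n_voxels``; labels without any finite voxel are dropped with a warning.
    """
    map_3d = np.asarray(map_3d, dtype=np.float64)
    atlas = np.asarray(atlas)
    if map_3d.shape != atlas.shape:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match map grid {map_3d.shape}"
        )
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    rows = []
    for lab in labels:
        vals = map_3d[atlas == lab]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            logger.warning("parcel %d has no finite voxels; dropped", int(lab))
            continue
        rows.append((int(lab), float(vals.mean()), int(len(vals))))
    df = pd.DataFrame(rows, columns=["parcel_id", "parcel_mean", "n_voxels"])
    if map_kind is not None:
        df.attrs["map_kind"] = map_kind
    return df


def cooks_distance(x, y):
    """Cook's distance per observation for the simple OLS of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return model.get_influence().cooks_distance[0]


@dataclass
class CorrelationResult:
    """One correlation with its Fisher-Z significance bookkeeping."""

    method: str
    r: float
    p: float
    fisher_z: float  # raw atanh(r)
    fisher_z_std: float  # atanh(r) * sqrt(n_used - 3)
    n_used: int
    removed_indices: list = field(default_factory=list)
    removal_rule: str = "none"
    critical_value: float = float("nan")  # two-tailed normal z criterion
    rho_critical: float = float("nan")  # |r| needed at n_used
    significant: bool = False


class CriticalValue(NamedTuple):
    z_crit: float  # two-tailed normal quantile on the standardized Z scale
    rho_crit: float  # corresponding |rho| threshold at n_used


def adjusted_critical_value(n_used, alpha=0.05):
    """Significance threshold for a single correlation via Fisher Z.

    The standardized statistic ``atanh(r) * sqrt(n_used - 3)`` is compared
    against the two-tailed normal quantile (1.96 at alpha = 0.05); the
    equivalent |rho| threshold, which grows as parcels are removed, is
    returned alongside.
    """
    if n_used < 4:
        raise ValueError("need n_used >= 4")
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return CriticalValue(z_crit=z, rho_crit=float(np.tanh(z / np.sqrt(n_used - 3))))


def _fisher(r, n):
    z = float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
    return z, z * np.sqrt(max(n - 3, 0))


class BetweenSubjectCorr(NamedTuple):
    full: CorrelationResult
    screened: CorrelationResult | None


def correlate_between_subjects(x, y, remove_influential=True, alpha=0.05):
    """Pearson correlation of per-subject scalars, with and without
    influential points (Cook's D > 4/n, one screening pass) removed."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y length mismatch")
    if len(x) < 4:
        raise ValueError("need at least 4 subjects")

    def _pearson(xs, ys, removed, rule):
        r, p = stats.pearsonr(xs, ys)
        z, z_std = _fisher(r, len(xs))
        if len(xs) >= 4:
            crit = adjusted_critical_value(len(xs), alpha)
        else:  # too few points for the Fisher-Z approximation
            crit = CriticalValue(float("nan"), float("nan"))
        return CorrelationResult(
            method="pearson",
            r=float(r),
            p=float(p),
            fisher_z=z,
            fisher_z_std=z_std,
            n_used=len(xs),
            removed_indices=removed,
            removal_rule=rule,
            critical_value=crit.z_crit,
            rho_critical=crit.rho_crit,
            significant=bool(p < alpha),
        )

    full = _pearson(x, y, [], "none")
    screened = None
    if remove_influential:
        d = cooks_distance(x, y)
        removed = np.where(d > 4.0 / len(x))[0]
        keep = np.setdiff1d(np.arange(len(x)), removed)
        if len(keep) < 3:
            raise ValueError("fewer than 3 subjects remain after influence removal")
        screened = _pearson(x[keep], y[keep], removed.tolist(), "cooks_4_over_n")
    return BetweenSubjectCorr(full=full, screened=screened)


def correlate_spatial(
    x_table,
    y_table,
    remove_outlier_parcels=True,
    alpha=0.05,
    max_removed_frac=0.25,
):
    """Spearman spatial correlation across parcels with outlier screening.

    ``x_table`` / ``y_table`` are parcel tables (DataFrames) with matching
    ``parcel_id``.  Outlier parcels are flagged by Cook's distance > 4/n on
    the rank-on-rank regression (consistent with the rank correlation) in a
    single pass, then Spearman rho is computed on the retained parcels.
    """
    x_table = x_table.sort_values("parcel_id").reset_index(drop=True)
    y_table = y_table.sort_values("parcel_id").reset_index(drop=True)
    if not np.array_equal(x_table["parcel_id"].values, y_table["parcel_id"].values):
        raise ValueError("parcel ids do not match between tables")
    x = x_table["parcel_mean"].to_numpy()
    y = y_table["parcel_mean"].to_numpy()
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 parcels")

    removed = []
    rule = "none"
    keep = np.arange(n)
    if remove_outlier_parcels:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d = cooks_distance(rx, ry)
        removed = np.where(d > 4.0 / n)[0]
        if len(removed) > max_removed_frac * n:
            logger.warning(
                "outlier screening removed %d/%d parcels (> %.0f%%)",
                len(removed),
                n,
                100 * max_removed_frac,
            )
        keep = np.setdiff1d(np.arange(n), removed)
        removed = x_table["parcel_id"].values[removed].tolist()
        rule = "cooks_4_over_n"

    rho, p = stats.spearmanr(x[keep], y[keep])
    z, z_std = _fisher(rho, len(keep))
    crit = adjusted_critical_value(len(keep), alpha)
    return CorrelationResult(
        method="spearman",
        r=float(rho),
        p=float(p),
        fisher_z=z,
        fisher_z_std=z_std,
        n_used=int(len(keep)),
        removed_indices=removed,
        removal_rule=rule,
        critical_value=crit.z_crit,
        rho_critical=crit.rho_crit,
        significant=bool(abs(z_std) > crit.z_crit),
    )


def fdr_adjust(p_values, alpha=0.05):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p_values = np.asarray(p_values, dtype=np.float64)
    _, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return p_adj
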
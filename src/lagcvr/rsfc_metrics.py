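"""Resting-state fluctuation-amplitude maps: ALFF, fALFF and mRSFA.

Per voxel the series is quadratically detrended, then

* ALFF  = mean one-sided Fourier amplitude inside the low-frequency band
  (default 0.01-0.1 Hz),
* fALFF = in-band amplitude sum / full non-DC amplitude sum (dimensionless,
  in [0, 1]),
* RSFA  = standard deviation of the ideal-bandpassed series; mRSFA divides
  by the voxel's original mean so it is dimensionless.

The bandpass is an ideal (boxcar) spectral filter for exact testability.
Optional Gaussian smoothing is applied to the 4-D data *before* metric
computation; smoothed and unsmoothed variants are both produced because
spatial correlations of ALFF/mRSFA with perfusion are sensitive to this
choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lagcvr.io_core import masked_gaussian_smooth

__all__ = ["RsfcMaps", "detrend_quadratic", "bandpass", "compute_metrics"]


@dataclass
class RsfcMaps:
    alff: np.ndarray
    falff: np.ndarray
    mrsfa: np.ndarray
    band_hz: tuple
    fwhm_mm: float
    mask: np.ndarray
    zero_mean_flag: np.ndarray | None = None


def detrend_quadratic(series):
    """Remove the least-squares quadratic trend along the last axis.

    Returns ``(residual, mean)`` where ``mean`` is the original series mean
    (retained for mRSFA normalization).  Idempotent on the residual.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    if n < 4:
        raise ValueError("need at least 4 time points for quadratic detrending")
    t = np.linspace(-1.0, 1.0, n)
    V = np.vander(t, 3, increasing=True)
    Q, _ = np.linalg.qr(V)
    flat = series.reshape(-1, n)
    resid = flat - (flat @ Q) @ Q.T
    return resid.reshape(series.shape), series.mean(axis=-1)


def _band_bins(n, tr_s, low_hz, high_hz):
    if high_hz >= 0.5 / tr_s:
        raise ValueError("high cutoff must be below the Nyquist frequency")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    in_band = (freqs >= low_hz) & (freqs <= high_hz)
    in_band[0] = False  # DC never passes
    if not in_band.any():
        raise ValueError("band contains no Fourier bins for this series length")
    return freqs, in_band


def bandpass(series, low_hz, high_hz, tr_s):
    """Ideal spectral bandpass along the last axis (DC removed)."""
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    _, keep = _band_bins(n, tr_s, low_hz, high_hz)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def compute_metrics(
    bold,
    mask,
    band_hz=(0.01, 0.1),
    tr_s=1.2,
    fwhm_mm=4.0,
    voxel_mm=(2.0, 2.0, 2.0),
    min_volumes=64,
):
    """Compute ALFF / fALFF / mRSFA maps for one resting segment.

    Returns ``{"unsmoothed": RsfcMaps, "smoothed": RsfcMaps | None}``; the
    smoothed variant applies a Gaussian kernel volume-by-volume before the
    metrics and is present whenever ``fwhm_mm > 0``.
    """
    bold = np.asarray(bold, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if bold.shape[-1] < min_volumes:
        raise ValueError(f"segment shorter than {min_volumes} volumes")

    out = {"unsmoothed": _metrics_one(bold, mask, band_hz, tr_s, 0.0)}
    if fwhm_mm > 0:
        sm = np.empty_like(bold)
        for v in range(bold.shape[-1]):
            sm[..., v] = masked_gaussian_smooth(
                bold[..., v], fwhm_mm, voxel_mm=voxel_mm, mask=mask
            )
        out["smoothed"] = _metrics_one(sm, mask, band_hz, tr_s, fwhm_mm)
    else:
        out["smoothed"] = None
    return out


def _metrics_one(bold, mask, band_hz, tr_s, fwhm_mm):
    n = bold.shape[-1]
    low, high = band_hz
    _, keep = _band_bins(n, tr_s, low, high)

    Y = bold[mask]
    resid, mean = detrend_quadratic(Y)
    amp = np.abs(np.fft.rfft(resid, axis=-1)) * 2.0 / n
    alff = amp[:, keep].mean(axis=-1)
    total = amp[:, 1:].sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        falff = amp[:, keep].sum(axis=-1) / total
    falff = np.where(total > 0, falff, 0.0)
    filtered = bandpass(resid, low, high, tr_s)
    rsfa = filtered.std(axis=-1)
    zero_mean = np.isclose(mean, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mrsfa = rsfa / mean
    mrsfa[zero_mean] = np.nan

    maps = {}
    for name, vals, fill in (
        ("alff", alff, np.nan),
        ("falff", falff, np.nan),
        ("mrsfa", mrsfa, np.nan),
        ("zero", zero_mean, False),
    ):
        m = np.full(mask.shape, fill, dtype=float if name != "zero" else bool)
        m[mask] = vals
        maps[name] = m
    return RsfcMaps(
        alff=maps["alff"],
        falff=maps["falff"],
        mrsfa=maps["mrsfa"],
        band_hz=tuple(band_hz),
        fwhm_mm=float(fwhm_mm),
        mask=mask,
        zero_mean_flag=maps["zero"],
    )
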
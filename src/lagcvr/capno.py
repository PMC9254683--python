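"""End-tidal CO2 processing: from a raw capnograph waveform to the family of
HRF-convolved, time-shifted, TR-resampled regressors used by the lagged GLM.

The chain is: detect one end-tidal peak per breath, linearly interpolate the
peaks into a continuous "tide" curve, subtract a baseline, convolve with a
canonical double-gamma hemodynamic response function, shift the result over a
symmetric lag grid (default +/-15 s in 0.3 s steps) and sample each shifted
copy at the volume acquisition times of the analyzed segment.

Sign convention (stated once, used everywhere): a *positive* lag delays the
regressor relative to the BOLD series, i.e. the BOLD response trails the CO2
change by ``lag`` seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gamma as gamma_dist

__all__ = [
    "CO2Trace",
    "PetCO2Series",
    "RegressorSet",
    "detect_end_tidal",
    "canonical_hrf",
    "build_regressors",
]


@dataclass
class CO2Trace:
    """Uniformly sampled CO2 waveform (mmHg) with scanner volume triggers."""

    time_s: np.ndarray
    co2_mmhg: np.ndarray
    sample_rate_hz: float = 1000.0
    trigger_times_s: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.co2_mmhg = np.asarray(self.co2_mmhg, dtype=np.float64)
        if self.time_s.shape != self.co2_mmhg.shape:
            raise ValueError("time_s and co2_mmhg must have equal length")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0 / self.sample_rate_hz, atol=1e-6):
                raise ValueError("trace is not uniformly sampled at sample_rate_hz")
        if np.any(self.co2_mmhg < -1e-9):
            raise ValueError("co2_mmhg must be non-negative")

    @classmethod
    def from_tsv(cls, path, sample_rate_hz=None, trigger_times_s=None):
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy()
        if sample_rate_hz is None:
            sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["co2_mmhg"].to_numpy(), sample_rate_hz, trigger_times_s)

    def to_tsv(self, path):
        pd.DataFrame({"time_s": self.time_s, "co2_mmhg": self.co2_mmhg}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class PetCO2Series:
    """End-tidal peak values with a baseline; linear interpolation between
    peaks defines the continuous end-tidal tide curve used downstream."""

    peak_times_s: np.ndarray
    petco2_mmhg: np.ndarray
    baseline_mmhg: float

    def __post_init__(self):
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=np.float64)
        self.petco2_mmhg = np.asarray(self.petco2_mmhg, dtype=np.float64)
        if len(self.peak_times_s) != len(self.petco2_mmhg):
            raise ValueError("peak times/values length mismatch")
        if np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def delta_mmhg(self):
        return self.petco2_mmhg - self.baseline_mmhg

    def tide(self, times_s):
        """Continuous end-tidal curve: linear interpolation with edge hold."""
        return np.interp(times_s, self.peak_times_s, self.petco2_mmhg)

    def with_baseline(self, baseline_mmhg):
        return PetCO2Series(self.peak_times_s, self.petco2_mmhg, float(baseline_mmhg))

    def baseline_from_windows(self, windows):
        """Recompute the baseline as the mean end-tidal value inside the given
        list of ``(start_s, end_s)`` windows (e.g. the rest portion of a task
        acquisition).  Falls back to all peaks if no peak falls inside."""
        sel = np.zeros(len(self.peak_times_s), dtype=bool)
        for lo, hi in windows:
            sel |= (self.peak_times_s >= lo) & (self.peak_times_s <= hi)
        if not sel.any():
            sel[:] = True
        return self.with_baseline(float(self.petco2_mmhg[sel].mean()))


def detect_end_tidal(
    trace: CO2Trace,
    min_breath_period_s: float = 2.0,
    min_prominence_mmhg: float = 3.0,
    baseline_windows=None,
    baseline_bounds=(30.0, 45.0),
    validate_baseline: bool = False,
) -> PetCO2Series:
    """Identify one expiratory end-tidal maximum per breath.

    Parameters
    ----------
    min_breath_period_s:
        Minimum separation between breaths; converted to a sample distance.
    min_prominence_mmhg:
        Minimum peak prominence; rejects ripple on the plateau.
    baseline_windows:
        Optional list of ``(start_s, end_s)`` windows over which the baseline
        (mean end-tidal value) is computed; default: all detected peaks.
    validate_baseline:
        If true, raise when the baseline falls outside ``baseline_bounds``
        (the physiological operating range for CVR studies).
    """
    if min_breath_period_s <= 0 or min_prominence_mmhg <= 0:
        raise ValueError("detection parameters must be positive")
    distance = max(1, int(round(min_breath_period_s * trace.sample_rate_hz)))
    idx, _ = find_peaks(trace.co2_mmhg, distance=distance, prominence=min_prominence_mmhg)
    if len(idx) == 0:
        raise ValueError(
            "no breaths detected: CO2 trace has no peaks with prominence "
            f">= {min_prominence_mmhg} mmHg"
        )
    peaks_t = trace.time_s[idx]
    peaks_v = trace.co2_mmhg[idx]
    series = PetCO2Series(peaks_t, peaks_v, float(peaks_v.mean()))
    if baseline_windows is not None:
        series = series.baseline_from_windows(baseline_windows)
    if validate_baseline and not (
        baseline_bounds[0] <= series.baseline_mmhg <= baseline_bounds[1]
    ):
        raise ValueError(
            f"baseline {series.baseline_mmhg:.1f} mmHg outside "
            f"{baseline_bounds} mmHg"
        )
    return series


def canonical_hrf(dt_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt_s`` over ``duration_s``.

    Response gamma with shape 6, undershoot gamma with shape 16 (unit scale),
    undershoot ratio 1/6; normalized to unit peak so the kernel's sampled
    values agree across sampling rates.  The convolution in
    :func:`build_regressors` divides by the kernel sum, giving unit
    steady-state gain so regressor units remain mmHg.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    h = gamma_dist.pdf(t, a=6.0, scale=1.0) - gamma_dist.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


@dataclass
class RegressorSet:
    """HRF-convolved, shifted, TR-sampled delta-PETCO2 regressors by lag."""

    lags_s: np.ndarray
    regressors: np.ndarray  # [n_lags, n_volumes]
    hrf_kernel: np.ndarray
    tr_s: float
    volume_times_s: np.ndarray
    baseline_mmhg: float
    edge_flags: np.ndarray = field(default=None)  # per-lag: edge-hold touched

    def __post_init__(self):
        self.lags_s = np.asarray(self.lags_s, dtype=np.float64)
        self.regressors = np.asarray(self.regressors, dtype=np.float64)
        if self.regressors.shape[0] != len(self.lags_s):
            raise ValueError("one regressor row per lag required")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("regressors contain non-finite values")
        if self.edge_flags is None:
            self.edge_flags = np.zeros(len(self.lags_s), dtype=bool)

    @property
    def lag0_index(self):
        return int(np.argmin(np.abs(self.lags_s)))

    def row(self, lag_s):
        i = int(np.argmin(np.abs(self.lags_s - lag_s)))
        if abs(self.lags_s[i] - lag_s) > 1e-9:
            raise ValueError(f"lag {lag_s} not on the lag grid")
        return self.regressors[i]

    def to_tsv(self, path, json_sidecar=None):
        cols = {f"lag_{lag:+.1f}": self.regressors[i] for i, lag in enumerate(self.lags_s)}
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        if json_sidecar is not None:
            payload = {
                "lags_s": self.lags_s.tolist(),
                "tr_s": self.tr_s,
                "baseline_mmhg": self.baseline_mmhg,
                "volume_times_s": self.volume_times_s.tolist(),
                "hrf": "double-gamma 6/16, ratio 1/6, 32 s, unit peak",
            }
            with open(json_sidecar, "w") as fh:
                json.dump(payload, fh, indent=2)


def _lag_grid(lag_limit_s, lag_step_s):
    n = lag_limit_s / lag_step_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("lag_step_s must divide lag_limit_s")
    n = int(round(n))
    return np.arange(-n, n + 1) * lag_step_s


def build_regressors(
    petco2: PetCO2Series,
    protocol=None,
    lag_limit_s: float = 15.0,
    lag_step_s: float = 0.3,
    volume_times_s=None,
    tr_s=None,
    n_volumes=None,
    n_discard=0,
    alignment_offset_s: float = 0.0,
) -> RegressorSet:
    """Build the full lagged regressor family for one analyzed segment.

    Pipeline order: interpolate the end-tidal tide curve onto a fine grid at
    ``lag_step_s`` resolution, subtract the baseline, convolve with the
    canonical HRF (unit steady-state gain), shift by each lag, and sample at
    the volume acquisition times of the analyzed segment (post-discard
    volumes).  Volume times come either from ``volume_times_s`` directly or
    from ``protocol`` / (``tr_s``, ``n_volumes``, ``n_discard``).
    """
    if volume_times_s is None:
        if protocol is not None:
            tr_s = protocol.tr_s
            n_volumes = protocol.n_volumes_total
            n_discard = protocol.n_discard
        if tr_s is None or n_volumes is None:
            raise ValueError("need volume_times_s, or a protocol, or tr_s+n_volumes")
        volume_times_s = alignment_offset_s + np.arange(n_volumes) * tr_s
        volume_times_s = volume_times_s[n_discard:]
    volume_times_s = np.asarray(volume_times_s, dtype=np.float64)
    if len(volume_times_s) == 0:
        raise ValueError("empty analyzed window")
    tr_out = tr_s if tr_s is not None else float(np.median(np.diff(volume_times_s)))

    lags = _lag_grid(lag_limit_s, lag_step_s)
    dt = lag_step_s
    hrf = canonical_hrf(dt)
    pad = lag_limit_s + len(hrf) * dt + dt
    t_fine = np.arange(volume_times_s[0] - pad, volume_times_s[-1] + lag_limit_s + dt, dt)
    delta_fine = petco2.tide(t_fine) - petco2.baseline_mmhg
    conv = np.convolve(delta_fine, hrf)[: len(t_fine)] / hrf.sum()

    rows = np.empty((len(lags), len(volume_times_s)))
    edge = np.empty(len(lags), dtype=bool)
    for i, lag in enumerate(lags):
        # positive lag delays the regressor: sample conv at (t - lag)
        rows[i] = np.interp(volume_times_s - lag, t_fine, conv)
        edge[i] = (volume_times_s[0] - lag < petco2.peak_times_s[0]) or (
            volume_times_s[-1] - lag > petco2.peak_times_s[-1]
        )
    return RegressorSet(
        lags_s=lags,
        regressors=rows,
        hrf_kernel=hrf,
        tr_s=float(tr_out),
        volume_times_s=volume_times_s,
        baseline_mmhg=petco2.baseline_mmhg,
        edge_flags=edge,
    )
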
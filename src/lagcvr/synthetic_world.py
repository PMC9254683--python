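"""Synthetic multi-subject study generator with known ground truth.

Emulates the acquisition structure of a breathing-task CVR study: five BOLD
segments of equal length (BH+REST, CDB+REST, REST, REST_BH, REST_CDB; TR
1.2 s, 8-min rest portions, first 10 volumes discarded, 390 analyzed), a
1000 Hz capnograph waveform with end-tidal structure per segment, spatially
varying ground-truth CVR amplitude and lag maps, a pCASL series (11 tag, 11
control, 1 M0) with planted CBF, a 48-region atlas split into 96 hemispheric
parcels and a gray-matter mask — all on one common grid, so registration
never enters.

The BOLD forward model mirrors the analysis GLM exactly: the voxel series is
``mean * (1 + amp/100 * regressor(lag))`` plus polynomial drift on the same
orthonormal basis the GLM removes, a motion-coupled random walk, spatially
smooth low-frequency physiological components, and white noise.  The
regressor uses the same HRF/convolution code path as the analysis, so at
zero noise every downstream estimator recovers its planted truth to
numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from lagcvr import capno, cvr_glm
from lagcvr.asl_cbf import AslParams

__all__ = [
    "SEGMENT_LABELS",
    "TimingConfig",
    "TaskProtocol",
    "GroundTruth",
    "SyntheticSubject",
    "make_protocol",
    "simulate_co2_trace",
    "simulate_bold",
    "simulate_pcasl",
    "make_atlas",
    "couple_fields",
    "make_truth",
    "make_subject",
    "write_subject",
]

SEGMENT_LABELS = ("BH+REST", "CDB+REST", "REST", "REST_BH", "REST_CDB")


# ---------------------------------------------------------------------------
# protocols


@dataclass
class TimingConfig:
    """Cue timings for the three acquisitions.

    Breath-hold (BH): 3 cycles of 24 s paced breathing (IN/OUT cues of 3 s),
    a hold (15 s by default — typical for breath-hold CVR protocols) and a
    free-breathing recovery.  Cued deep breathing (CDB): 2 blocks of 8 fast
    deep breaths (2 s cues) plus recovery.  Every segment spans the same
    total duration as the 8-min rest segment.
    """

    tr_s: float = 1.2
    rest_duration_s: float = 480.0
    n_discard: int = 10
    bh_cycles: int = 3
    bh_paced_s: float = 24.0
    bh_cue_s: float = 3.0
    bh_hold_s: float = 15.0
    bh_recover_s: float = 9.0
    cdb_cycles: int = 2
    cdb_breaths: int = 8
    cdb_cue_s: float = 2.0
    cdb_recover_s: float = 22.0


@dataclass
class Event:
    onset_s: float
    duration_s: float
    kind: str  # paced_in, paced_out, hold, deep_in, deep_out, recover, rest


@dataclass
class TaskProtocol:
    segment_label: str
    events: list
    tr_s: float
    n_volumes_total: int
    n_discard: int

    def __post_init__(self):
        last_end = -1e-9
        for ev in self.events:
            if ev.duration_s < 0:
                raise ValueError(f"negative event duration at onset {ev.onset_s}")
            if ev.onset_s < last_end - 1e-9:
                raise ValueError("events overlap or are unsorted")
            last_end = ev.onset_s + ev.duration_s
        if self.n_discard >= self.n_volumes_total:
            raise ValueError("discard count must be below total volume count")

    @property
    def n_volumes_analyzed(self):
        return self.n_volumes_total - self.n_discard

    @property
    def duration_s(self):
        return self.n_volumes_total * self.tr_s

    @property
    def n_holds(self):
        return sum(1 for ev in self.events if ev.kind == "hold")

    @property
    def n_deep_blocks(self):
        blocks, prev_deep = 0, False
        for ev in self.events:
            deep = ev.kind in ("deep_in", "deep_out")
            if deep and not prev_deep:
                blocks += 1
            prev_deep = deep
        return blocks

    def rest_windows(self):
        return [
            (ev.onset_s, ev.onset_s + ev.duration_s)
            for ev in self.events
            if ev.kind == "rest"
        ]


def make_protocol(segment_label, timing: TimingConfig | None = None) -> TaskProtocol:
    """Event list for one data segment (all five share a total duration)."""
    timing = timing or TimingConfig()
    if timing.tr_s <= 0 or timing.rest_duration_s < 0:
        raise ValueError("TR must be positive and rest duration non-negative")
    n_total = int(round(timing.rest_duration_s / timing.tr_s))
    if n_total <= 0:
        raise ValueError("segment has no volumes: rest duration too short")
    if timing.n_discard >= n_total:
        raise ValueError("discard count must be below total volume count")
    duration = n_total * timing.tr_s

    events: list[Event] = []
    t = 0.0

    def add(kind, dur):
        nonlocal t
        events.append(Event(round(t, 6), dur, kind))
        t += dur

    if segment_label == "BH+REST":
        n_pairs = int(round(timing.bh_paced_s / (2 * timing.bh_cue_s)))
        for _ in range(timing.bh_cycles):
            for _ in range(n_pairs):
                add("paced_in", timing.bh_cue_s)
                add("paced_out", timing.bh_cue_s)
            add("hold", timing.bh_hold_s)
            add("recover", timing.bh_recover_s)
    elif segment_label == "CDB+REST":
        for _ in range(timing.cdb_cycles):
            for _ in range(timing.cdb_breaths):
                add("deep_in", timing.cdb_cue_s)
                add("deep_out", timing.cdb_cue_s)
            add("recover", timing.cdb_recover_s)
    elif segment_label not in SEGMENT_LABELS:
        raise ValueError(f"unknown segment label {segment_label!r}")

    if t > duration + 1e-9:
        raise ValueError("breathing task longer than the segment")
    add("rest", duration - t)
    return TaskProtocol(
        segment_label=segment_label,
        events=events,
        tr_s=timing.tr_s,
        n_volumes_total=n_total,
        n_discard=timing.n_discard,
    )


# ---------------------------------------------------------------------------
# CO2 waveform


def simulate_co2_trace(
    protocol: TaskProtocol,
    baseline_mmhg: float = 38.0,
    bh_rise_mmhg: float = 10.0,
    cdb_dip_mmhg: float = 8.0,
    breath_period_s: float = 4.0,
    rest_fluct_mmhg: float = 1.0,
    noise_sd: float = 0.2,
    sample_rate_hz: float = 1000.0,
    recover_tau_s: float = 8.0,
    seed=None,
):
    """Raised-cosine breath train with planted end-tidal structure.

    Returns ``(trace, petco2_true)``.  Each breath is a raised-cosine hump
    from a near-zero inspiratory trough to its end-tidal peak, giving the
    detector one unambiguous maximum per breath.  Holds suspend breathing and
    make the first post-hold peak exactly ``baseline + bh_rise``; deep-
    breathing blocks ramp peaks down to exactly ``baseline - cdb_dip``; rest
    and paced breaths carry a slow AR(1) end-tidal fluctuation of SD
    ``rest_fluct_mmhg`` (the natural variability that rest-only CVR modeling
    relies on).  ``noise_sd`` jitters the *realized* peaks only; the returned
    ``petco2_true`` is the noiseless truth.
    """
    if not (10.0 < baseline_mmhg < 80.0):
        raise ValueError("baseline outside physiological range")
    stochastic = (noise_sd > 0) or (rest_fluct_mmhg > 0)
    if stochastic and seed is None:
        raise ValueError("seed required when noise_sd or rest_fluct_mmhg > 0")
    rng = np.random.default_rng(seed)

    fs = sample_rate_hz
    duration = protocol.duration_s
    n_samples = int(round(duration * fs))

    # schedule breaths: (start_index, n_samples, kind, context)
    breaths = []
    pending_hold_end = None
    events = protocol.events
    i = 0
    while i < len(events):
        ev = events[i]
        if ev.kind in ("paced_in", "deep_in"):
            out = events[i + 1] if i + 1 < len(events) else None
            period = ev.duration_s + (out.duration_s if out is not None else 0.0)
            breaths.append([ev.onset_s, period, "deep" if ev.kind == "deep_in" else "paced"])
            i += 2
            continue
        if ev.kind == "hold":
            pending_hold_end = ev.onset_s + ev.duration_s
            i += 1
            continue
        if ev.kind in ("rest", "recover"):
            t0 = ev.onset_s
            end = ev.onset_s + ev.duration_s
            while t0 + breath_period_s <= end + 1e-9:
                kind = ev.kind
                breaths.append([t0, breath_period_s, kind])
                t0 += breath_period_s
            i += 1
            continue
        i += 1

    # assign planted peak values in chronological order
    breaths.sort(key=lambda b: b[0])
    fluct = 0.0
    a = 0.9  # AR(1) coefficient per breath
    innov_sd = rest_fluct_mmhg * np.sqrt(1 - a**2)
    deep_block = []  # indices of current deep block
    peak_true = np.zeros(len(breaths))
    hold_ends = sorted(
        ev.onset_s + ev.duration_s for ev in events if ev.kind == "hold"
    )
    deep_ends = []
    prev_deep_end = None
    last_dip_end = None
    for k, (t0, period, kind) in enumerate(breaths):
        t_peak = t0 + period / 2.0
        if kind == "deep":
            deep_block.append(k)
            continue  # values assigned when the block closes
        if deep_block:
            nblk = len(deep_block)
            for j, kk in enumerate(deep_block):
                peak_true[kk] = baseline_mmhg - cdb_dip_mmhg * (j + 1) / nblk
            last_dip_end = breaths[deep_block[-1]][0] + breaths[deep_block[-1]][1]
            deep_block = []
        recent_hold = [h for h in hold_ends if t0 >= h - 1e-9]
        after_hold = recent_hold and (t0 - recent_hold[-1]) < recover_tau_s * 3
        after_dip = last_dip_end is not None and (t0 - last_dip_end) < recover_tau_s * 3
        if kind == "recover" and after_hold:
            h_end = recent_hold[-1]
            if t0 - h_end < period:  # first exhale after the hold
                peak_true[k] = baseline_mmhg + bh_rise_mmhg
            else:
                peak_true[k] = baseline_mmhg + bh_rise_mmhg * np.exp(
                    -(t_peak - h_end) / recover_tau_s
                )
        elif kind == "recover" and after_dip:
            peak_true[k] = baseline_mmhg - cdb_dip_mmhg * np.exp(
                -(t_peak - last_dip_end) / recover_tau_s
            )
        else:
            if rest_fluct_mmhg > 0:
                fluct = a * fluct + rng.normal(0.0, innov_sd)
            peak_true[k] = baseline_mmhg + fluct
    if deep_block:  # block runs to the end of the segment
        nblk = len(deep_block)
        for j, kk in enumerate(deep_block):
            peak_true[kk] = baseline_mmhg - cdb_dip_mmhg * (j + 1) / nblk

    peak_real = peak_true.copy()
    if noise_sd > 0:
        peak_real = peak_real + rng.normal(0.0, noise_sd, size=len(breaths))
    peak_real = np.maximum(peak_real, 0.0)

    co2 = np.zeros(n_samples)
    peak_times = np.empty(len(breaths))
    for k, (t0, period, _) in enumerate(breaths):
        i0 = int(round(t0 * fs))
        nb = int(round(period * fs))
        i1 = min(i0 + nb, n_samples)
        kk = np.arange(i1 - i0)
        co2[i0:i1] = peak_real[k] * 0.5 * (1.0 - np.cos(2.0 * np.pi * kk / nb))
        peak_times[k] = (i0 + nb // 2) / fs

    trace = capno.CO2Trace(
        time_s=np.arange(n_samples) / fs,
        co2_mmhg=co2,
        sample_rate_hz=fs,
        trigger_times_s=np.arange(protocol.n_volumes_total) * protocol.tr_s,
    )
    truth = capno.PetCO2Series(peak_times, peak_true, baseline_mmhg)
    truth = truth.baseline_from_windows(protocol.rest_windows())
    return trace, truth


# ---------------------------------------------------------------------------
# ground truth fields


def _smooth_field(shape, rng, sigma_vox=2.5):
    f = gaussian_filter(rng.standard_normal(shape), sigma_vox)
    return (f - f.mean()) / f.std()


@dataclass
class GroundTruth:
    """Planted quantities against which recovery is tested."""

    cvr_amp_map: np.ndarray  # %BOLD/mmHg
    lag_map: np.ndarray  # seconds, on the lag grid
    cbf_map: np.ndarray  # ml/100 g/min
    coupling_rho: float
    petco2_true: dict  # segment label -> PetCO2Series
    seed: int
    gm_mask: np.ndarray = None
    mean_map: np.ndarray = None


def couple_fields(base_values, rho, seed=None):
    """A vector whose expected Spearman correlation with ``base_values`` is
    ``rho``.

    The base is rank-transformed to normal scores ``z``; the output is
    ``r_p * z + sqrt(1 - r_p^2) * e`` with ``e`` a standardized Gaussian
    residualized against ``z`` and ``r_p = 2 sin(pi rho / 6)``, the
    bivariate-normal Pearson level whose grade (Spearman) correlation equals
    ``rho``.  ``rho = 1`` maps to ``r_p = 1``: identical ranks.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    base = np.asarray(base_values, dtype=np.float64)
    n = len(base)
    ranks = stats.rankdata(base)
    z = stats.norm.ppf((ranks - 0.5) / n)
    z = (z - z.mean()) / z.std()
    r_p = 2.0 * np.sin(np.pi * rho / 6.0)
    if abs(r_p) >= 1.0 - 1e-12:
        return np.sign(r_p) * z
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    e = e - z * (e @ z) / (z @ z)  # orthogonalize so the planted level is exact
    e = (e - e.mean()) / e.std()
    return r_p * z + np.sqrt(1.0 - r_p**2) * e


def make_atlas(grid_shape=(24, 24, 12), n_regions=48):
    """Ellipsoidal brain split into left/right hemispheres, each partitioned
    into ``n_regions`` equal-count parcels (labels 1..2*n_regions).

    Partitioning slices the in-mask voxels into near-equal-count blocks along
    x, then y, then z, so no parcel is ever empty.  Returns
    ``(atlas, gm_mask)``.
    """
    shape = tuple(int(s) for s in grid_shape)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0 - 0.5, 0.5) for s in shape]
    ii = np.indices(shape).astype(float)
    r2 = sum(((ii[d] - center[d]) / semi[d]) ** 2 for d in range(3))
    brain = r2 <= 1.0

    atlas = np.zeros(shape, dtype=np.int32)
    fa, fb, fc = _factor_triple(n_regions)
    for hemi, hemi_mask in enumerate(
        (brain & (ii[0] < center[0]), brain & (ii[0] >= center[0]))
    ):
        coords = np.argwhere(hemi_mask)
        if len(coords) < n_regions:
            raise ValueError(
                f"grid too small: hemisphere has {len(coords)} voxels "
                f"for {n_regions} regions"
            )
        label = hemi * n_regions + 1
        order_x = coords[np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))]
        for chunk_x in np.array_split(order_x, fa):
            cx = chunk_x[np.lexsort((chunk_x[:, 2], chunk_x[:, 0], chunk_x[:, 1]))]
            for chunk_y in np.array_split(cx, fb):
                cy = chunk_y[np.lexsort((chunk_y[:, 0], chunk_y[:, 1], chunk_y[:, 2]))]
                for chunk_z in np.array_split(cy, fc):
                    atlas[tuple(chunk_z.T)] = label
                    label += 1
    return atlas, atlas > 0


def _factor_triple(n):
    best = (1, 1, n)
    best_spread = n
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(np.sqrt(m)) + 1):
            if m % b:
                continue
            c = m // b
            spread = c - a
            if spread < best_spread:
                best, best_spread = (a, b, c), spread
    return tuple(sorted(best))


def make_truth(
    grid_shape=(24, 24, 12),
    seed=0,
    coupling_rho=0.6,
    amp_range=(0.1, 0.4),
    amp_mean=0.25,
    amp_sd=0.06,
    lag_sd_s=3.0,
    lag_max_s=9.0,
    lag_step_s=0.3,
    cbf_mean=60.0,
    cbf_sd=15.0,
    mean_signal=1000.0,
    n_regions=48,
):
    """Plant smooth CVR amplitude / lag / CBF fields with known coupling.

    CBF parcel means are coupled to CVR-amplitude parcel means at Spearman
    level ``coupling_rho`` through :func:`couple_fields`; within-parcel CBF
    variation is smooth and zero-mean so parcel means carry the coupling.
    """
    ss = np.random.SeedSequence(seed)
    r_amp, r_lag, r_cbf, r_mean = [np.random.default_rng(s) for s in ss.spawn(4)]
    atlas, gm_mask = make_atlas(grid_shape, n_regions)

    amp = amp_mean + amp_sd * _smooth_field(grid_shape, r_amp)
    amp = np.clip(amp, *amp_range)
    lag = np.clip(lag_sd_s * _smooth_field(grid_shape, r_lag), -lag_max_s, lag_max_s)
    lag = np.round(lag / lag_step_s) * lag_step_s

    labels = np.unique(atlas[atlas > 0])
    parcel_amp = np.array([amp[atlas == lab].mean() for lab in labels])
    coupled = couple_fields(parcel_amp, coupling_rho, seed=r_cbf.integers(2**31))
    cbf = np.zeros(grid_shape)
    for lab, val in zip(labels, cbf_mean + cbf_sd * coupled):
        cbf[atlas == lab] = val
    within = 3.0 * _smooth_field(grid_shape, r_cbf, sigma_vox=1.5)
    cbf = np.where(gm_mask, np.clip(cbf + within, 5.0, None), 0.0)

    mean_map = np.where(
        gm_mask, mean_signal * (1.0 + 0.1 * _smooth_field(grid_shape, r_mean)), 0.0
    )
    amp = np.where(gm_mask, amp, 0.0)
    lag = np.where(gm_mask, lag, 0.0)
    return (
        GroundTruth(
            cvr_amp_map=amp,
            lag_map=lag,
            cbf_map=cbf,
            coupling_rho=float(coupling_rho),
            petco2_true={},
            seed=int(seed),
            gm_mask=gm_mask,
            mean_map=mean_map,
        ),
        atlas,
    )


# ---------------------------------------------------------------------------
# BOLD forward model


def simulate_bold(
    truth: GroundTruth,
    petco2_true: capno.PetCO2Series,
    protocol: TaskProtocol,
    drift_coeffs=(5.0, -3.0, 2.0, 1.0),
    motion_amplitude=0.02,
    motion_coupling=2.5,
    physio_pct=0.2,
    n_physio=3,
    noise_sd=0.0,
    lag_limit_s=15.0,
    lag_step_s=0.3,
    seed=None,
):
    """Forward BOLD model on the common grid; returns ``(bold, motion_df)``.

    ``noise_sd`` is thermal noise in raw signal units (mean 1000 at tSNR 50
    gives 20); ``physio_pct`` is the total standard deviation, in percent of
    the mean signal, of ``n_physio`` spatially smooth low-frequency
    components shared across voxels — the structured fluctuation that does
    not average away over parcels.
    """
    rng = np.random.default_rng(seed)
    mask = truth.gm_mask
    lag_max = float(np.abs(truth.lag_map[mask]).max()) if mask.any() else 0.0
    if lag_max > lag_limit_s + 1e-9:
        raise ValueError("planted lag outside the representable lag range")

    n_total = protocol.n_volumes_total
    regset = capno.build_regressors(
        petco2_true,
        lag_limit_s=lag_limit_s,
        lag_step_s=lag_step_s,
        tr_s=protocol.tr_s,
        n_volumes=n_total,
        n_discard=0,
    )

    amp = truth.cvr_amp_map[mask]
    lagv = truth.lag_map[mask]
    mean = truth.mean_map[mask]
    n_vox = mask.sum()

    Y = np.empty((n_vox, n_total))
    for lag in np.unique(lagv):
        row = regset.row(lag)
        sel = lagv == lag
        Y[sel] = mean[sel, None] * (1.0 + amp[sel, None] / 100.0 * row[None, :])

    # polynomial drift on the same orthonormal basis the GLM removes,
    # demeaned over the analyzed window so the fitted intercept stays the
    # voxel mean (the quantity CVR scaling divides by)
    if drift_coeffs is not None and len(drift_coeffs):
        basis = cvr_glm.drift_basis(n_total, len(drift_coeffs))
        coeffs = np.asarray(drift_coeffs) * rng.normal(
            1.0, 0.3, size=(n_vox, len(drift_coeffs))
        )
        drift = coeffs @ basis.T
        drift -= drift[:, protocol.n_discard :].mean(axis=1, keepdims=True)
        Y += drift

    # motion random walk + voxelwise coupling
    motion = np.cumsum(rng.normal(0.0, motion_amplitude, size=(n_total, 6)), axis=0)
    if motion_amplitude > 0 and motion_coupling > 0:
        W = rng.normal(0.0, motion_coupling, size=(n_vox, 6))
        Y += W @ motion.T

    # smooth low-frequency physiological components
    if physio_pct > 0 and n_physio > 0:
        from lagcvr.rsfc_metrics import bandpass

        comps = rng.standard_normal((n_physio, n_total))
        comps = bandpass(comps, 0.01, 0.1, protocol.tr_s)
        comps /= comps.std(axis=-1, keepdims=True)
        w_sd = physio_pct / 100.0 / np.sqrt(n_physio)
        weights = np.stack(
            [
                _smooth_field(mask.shape, rng)[mask] * w_sd * mean
                for _ in range(n_physio)
            ],
            axis=1,
        )
        Y += weights @ comps

    if noise_sd > 0:
        Y += rng.normal(0.0, noise_sd, size=Y.shape)

    bold = np.zeros(mask.shape + (n_total,))
    bold[mask] = Y
    motion_df = pd.DataFrame(
        motion, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    )
    return bold, motion_df


# ---------------------------------------------------------------------------
# pCASL forward model


def simulate_pcasl(
    truth: GroundTruth,
    asl_params: AslParams | None = None,
    m0_value=1000.0,
    base_frac=0.1,
    n_pairs=11,
    noise_sd=2.0,
    seed=None,
):
    """Tag/control/M0 series whose mean control-minus-tag difference equals
    the forward kinetic model at the planted CBF.

    Order is tag-first interleaved with the M0 volume last; returns
    ``(series, meta)`` with ``meta`` declaring the pairing order and M0
    index.
    """
    if m0_value <= 0:
        raise ValueError("M0 must be positive")
    params = asl_params or AslParams()
    rng = np.random.default_rng(seed)
    mask = truth.gm_mask
    m0 = np.where(mask, m0_value, 0.0)
    delta_m = truth.cbf_map * m0 * params.cbf_scale()
    base = base_frac * m0

    shape = mask.shape
    series = np.zeros(shape + (2 * n_pairs + 1,))
    for k in range(n_pairs):
        tag = base - delta_m / 2.0
        ctrl = base + delta_m / 2.0
        if noise_sd > 0:
            tag = tag + rng.normal(0.0, noise_sd, size=shape) * mask
            ctrl = ctrl + rng.normal(0.0, noise_sd, size=shape) * mask
        series[..., 2 * k] = tag
        series[..., 2 * k + 1] = ctrl
    series[..., -1] = m0
    meta = {"pairing_order": "tc", "m0_index": 2 * n_pairs, "n_pairs": n_pairs}
    return series, meta


# ---------------------------------------------------------------------------
# whole subjects


@dataclass
class SyntheticSubject:
    subject_id: int
    bold_segments: dict  # label -> 4D array
    co2_traces: dict  # label -> CO2Trace
    motion_params: dict  # label -> DataFrame
    pcasl_series: np.ndarray
    pcasl_meta: dict
    atlas: np.ndarray
    gm_mask: np.ndarray
    protocols: dict  # label -> TaskProtocol
    truth: GroundTruth
    affine: np.ndarray
    tr_s: float


def make_subject(
    seed,
    grid_shape=(24, 24, 12),
    voxel_mm=2.0,
    timing: TimingConfig | None = None,
    coupling_rho=0.6,
    tsnr=50.0,
    co2_noise_sd=0.2,
    physio_pct=0.2,
    motion_amplitude=0.02,
    segments=SEGMENT_LABELS,
    subject_id=0,
    mean_signal=1000.0,
    asl_params: AslParams | None = None,
    noiseless=False,
):
    """Generate one complete synthetic subject (all requested segments).

    ``noiseless=True`` switches off thermal noise, physiological components,
    motion and CO2 measurement noise (the planted end-tidal fluctuation, part
    of the ground truth, remains), for forward/inverse closure checks.
    """
    timing = timing or TimingConfig()
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.spawn(2 + 2 * len(segments)))
    truth, atlas = make_truth(
        grid_shape,
        seed=seed,
        coupling_rho=coupling_rho,
        mean_signal=mean_signal,
    )
    noise_sd = 0.0 if noiseless else mean_signal / tsnr
    bold_segments, co2_traces, motions, protocols = {}, {}, {}, {}
    for label in segments:
        protocol = make_protocol(label, timing)
        trace, pet_true = simulate_co2_trace(
            protocol,
            noise_sd=0.0 if noiseless else co2_noise_sd,
            seed=next(seeds),
        )
        bold, motion_df = simulate_bold(
            truth,
            pet_true,
            protocol,
            motion_amplitude=0.0 if noiseless else motion_amplitude,
            physio_pct=0.0 if noiseless else physio_pct,
            noise_sd=noise_sd,
            seed=next(seeds),
        )
        truth.petco2_true[label] = pet_true
        bold_segments[label] = bold
        co2_traces[label] = trace
        motions[label] = motion_df
        protocols[label] = protocol
    pcasl, meta = simulate_pcasl(
        truth,
        asl_params=asl_params,
        noise_sd=0.0 if noiseless else 2.0,
        seed=next(seeds),
    )
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return SyntheticSubject(
        subject_id=subject_id,
        bold_segments=bold_segments,
        co2_traces=co2_traces,
        motion_params=motions,
        pcasl_series=pcasl,
        pcasl_meta=meta,
        atlas=atlas,
        gm_mask=truth.gm_mask,
        protocols=protocols,
        truth=truth,
        affine=affine,
        tr_s=timing.tr_s,
    )


def write_subject(subject: SyntheticSubject, out_dir):
    """Write one subject to disk: NIfTI volumes, TSV traces/motion, JSON
    truth metadata plus truth maps as NIfTI."""
    from pathlib import Path

    from lagcvr.io_core import write_json, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = subject.affine
    safe = {label: label.replace("+", "_") for label in subject.bold_segments}
    for label, bold in subject.bold_segments.items():
        write_volume(out / f"bold_{safe[label]}.nii.gz", bold, aff)
        subject.co2_traces[label].to_tsv(out / f"co2_{safe[label]}.tsv")
        subject.motion_params[label].to_csv(
            out / f"motion_{safe[label]}.tsv", sep="\t", index=False
        )
    write_volume(out / "pcasl.nii.gz", subject.pcasl_series, aff)
    write_json(out / "pcasl.json", subject.pcasl_meta)
    write_volume(out / "atlas.nii.gz", subject.atlas.astype(float), aff)
    write_volume(out / "gm_mask.nii.gz", subject.gm_mask.astype(float), aff)
    t = subject.truth
    write_volume(out / "truth_cvr_amp.nii.gz", t.cvr_amp_map, aff)
    write_volume(out / "truth_lag.nii.gz", t.lag_map, aff)
    write_volume(out / "truth_cbf.nii.gz", t.cbf_map, aff)
    write_json(
        out / "truth.json",
        {
            "seed": t.seed,
            "coupling_rho": t.coupling_rho,
            "tr_s": subject.tr_s,
            "segments": list(subject.bold_segments),
        },
    )
    return out
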
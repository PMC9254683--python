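"""End-to-end orchestration: simulate -> end-tidal -> CVR (both schemes, all
segments) -> CBF -> resting-state metrics -> parcel statistics -> group
inference, with a single long-format report.

Every stage runs through the public module APIs, so the report produced here
is exactly what a user scripting the stages by hand would obtain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lagcvr import asl_cbf, capno, cvr_glm, group_inference, parcel_stats, rsfc_metrics
from lagcvr.io_core import StudyConfig, provenance, write_json, write_table
from lagcvr.synthetic_world import SEGMENT_LABELS, TimingConfig, make_subject

logger = logging.getLogger("lagcvr")

__all__ = ["SubjectResult", "StudyReport", "analyze_subject", "run_pipeline"]

REST_SEGMENTS = ("REST", "REST_BH", "REST_CDB")


@dataclass
class SubjectResult:
    subject_id: int
    cvr: dict  # (segment, scheme) -> CvrResult
    cbf: asl_cbf.CbfMap
    rsfc: dict  # segment -> {"smoothed": RsfcMaps|None, "unsmoothed": RsfcMaps}
    spatial_rows: pd.DataFrame
    gm_rows: pd.DataFrame
    recovery: dict


@dataclass
class StudyReport:
    config: StudyConfig
    spatial: pd.DataFrame  # subject x segment x scheme spatial correlations
    gm: pd.DataFrame  # per-subject GM medians
    between: pd.DataFrame  # between-subject correlations (10 tests + FDR)
    anova: group_inference.PermAnovaResult
    outlier_screen: group_inference.OutlierScreenResult
    pairwise: pd.DataFrame
    rsfc_spatial: pd.DataFrame
    recovery: pd.DataFrame
    n_subjects: int = 0
    outputs: dict = field(default_factory=dict)

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(out / "spatial_correlations.tsv", self.spatial)
        write_table(out / "gm_values.tsv", self.gm)
        write_table(out / "between_subject.tsv", self.between)
        write_table(out / "pairwise_contrasts.tsv", self.pairwise)
        write_table(out / "rsfc_spatial.tsv", self.rsfc_spatial)
        write_table(out / "recovery.tsv", self.recovery)
        a = self.anova
        write_json(
            out / "anova.json",
            {
                "f_scheme": a.f_a,
                "f_segment": a.f_b,
                "f_interaction": a.f_ab,
                "df": a.df,
                "p_scheme": a.p_a,
                "p_segment": a.p_b,
                "p_interaction": a.p_ab,
                "n_perm": a.n_perm,
                "seed": a.seed,
                "provenance": provenance(self.config, self.config.seed, "anova"),
            },
        )
        return out


def analyze_subject(subject, config: StudyConfig | None = None):
    """Run the full single-subject analysis against the subject's own atlas.

    Returns a :class:`SubjectResult` holding CVR maps for every
    segment x scheme, the quantified CBF map, resting-state metric maps for
    the rest segments, parcelwise spatial-correlation rows and gray-matter
    median rows.
    """
    config = config or StudyConfig()
    atlas, gm = subject.atlas, subject.gm_mask
    truth = subject.truth

    # --- CBF ---------------------------------------------------------------
    delta_m, m0, n_pairs = asl_cbf.tag_control_diff(
        subject.pcasl_series,
        pairing_order=subject.pcasl_meta["pairing_order"],
        m0_index=subject.pcasl_meta["m0_index"],
    )
    cbf = asl_cbf.quantify_cbf(delta_m, m0, mask=gm, n_pairs_used=n_pairs)
    cbf_parcels = parcel_stats.parcel_means(cbf.cbf, atlas, map_kind="cbf")

    cvr_results = {}
    spatial_rows = []
    gm_rows = []
    recovery = {}
    for label, bold in subject.bold_segments.items():
        protocol = subject.protocols[label]
        trace = subject.co2_traces[label]
        pet = capno.detect_end_tidal(
            trace, baseline_windows=protocol.rest_windows()
        )
        regset = capno.build_regressors(
            pet,
            protocol,
            lag_limit_s=config.lag_limit_s,
            lag_step_s=config.lag_step_s,
        )
        motion = subject.motion_params[label].to_numpy()[protocol.n_discard :]
        analyzed = bold[..., protocol.n_discard :]
        if np.allclose(motion, motion.mean(axis=0)):
            motion = None
        for scheme, fn in (("No-Opt", cvr_glm.cvr_no_opt), ("Lag-Opt", cvr_glm.cvr_lag_opt)):
            res = fn(analyzed, gm, regset, motion_table=motion)
            cvr_results[(label, scheme)] = res
            tab = parcel_stats.parcel_means(res.cvr_amp, atlas, map_kind="cvr_amp")
            corr = parcel_stats.correlate_spatial(cbf_parcels, tab)
            spatial_rows.append(
                {
                    "subject": subject.subject_id,
                    "segment": label,
                    "scheme": scheme,
                    "metric": "cvr_amp",
                    "rho": corr.r,
                    "fisher_z": corr.fisher_z,
                    "fisher_z_std": corr.fisher_z_std,
                    "n_used": corr.n_used,
                    "n_removed": len(corr.removed_indices),
                    "significant": corr.significant,
                }
            )
            gm_rows.append(
                {
                    "subject": subject.subject_id,
                    "segment": label,
                    "scheme": scheme,
                    "gm_cvr": parcel_stats.gm_median(res.cvr_amp, gm),
                    "gm_cbf": parcel_stats.gm_median(cbf.cbf, gm),
                }
            )
            err = np.abs(res.cvr_amp[gm] - truth.cvr_amp_map[gm]) / truth.cvr_amp_map[gm]
            rec = {"amp_rel_err_median": float(np.nanmedian(err))}
            if scheme == "Lag-Opt":
                rec["lag_abs_err_median"] = float(
                    np.median(np.abs(res.lag_s[gm] - truth.lag_map[gm]))
                )
            recovery[(label, scheme)] = rec

    # --- resting-state metrics vs CBF -------------------------------------
    rsfc = {}
    for label in subject.bold_segments:
        if label not in REST_SEGMENTS:
            continue
        protocol = subject.protocols[label]
        analyzed = subject.bold_segments[label][..., protocol.n_discard :]
        rsfc[label] = rsfc_metrics.compute_metrics(
            analyzed,
            gm,
            band_hz=config.band_hz,
            tr_s=config.tr_s,
            fwhm_mm=config.fwhm_mm,
            voxel_mm=(config.voxel_mm,) * 3,
        )
        for variant, maps in rsfc[label].items():
            if maps is None:
                continue
            for metric in ("alff", "falff", "mrsfa"):
                tab = parcel_stats.parcel_means(getattr(maps, metric), atlas, metric)
                corr = parcel_stats.correlate_spatial(cbf_parcels, tab)
                spatial_rows.append(
                    {
                        "subject": subject.subject_id,
                        "segment": label,
                        "scheme": variant,
                        "metric": metric,
                        "rho": corr.r,
                        "fisher_z": corr.fisher_z,
                        "fisher_z_std": corr.fisher_z_std,
                        "n_used": corr.n_used,
                        "n_removed": len(corr.removed_indices),
                        "significant": corr.significant,
                    }
                )

    return SubjectResult(
        subject_id=subject.subject_id,
        cvr=cvr_results,
        cbf=cbf,
        rsfc=rsfc,
        spatial_rows=pd.DataFrame(spatial_rows),
        gm_rows=pd.DataFrame(gm_rows),
        recovery=recovery,
    )


def run_pipeline(config: StudyConfig | None = None, segments=SEGMENT_LABELS):
    """Simulate and analyze a whole study, returning a :class:`StudyReport`.

    The seed in ``config`` drives every stochastic stage; identical configs
    regenerate identical reports.
    """
    config = config or StudyConfig()
    timing = TimingConfig(
        tr_s=config.tr_s,
        rest_duration_s=config.rest_duration_s,
        n_discard=config.n_discard,
    )
    results = []
    for s in range(config.n_subjects):
        subject = make_subject(
            seed=int(np.random.SeedSequence([config.seed, s]).generate_state(1)[0] % 2**31),
            grid_shape=config.grid_shape,
            voxel_mm=config.voxel_mm,
            timing=timing,
            coupling_rho=config.coupling_rho,
            tsnr=config.tsnr,
            segments=segments,
            subject_id=s,
        )
        logger.info("analyzing subject %d", s)
        results.append(analyze_subject(subject, config))

    spatial = pd.concat([r.spatial_rows for r in results], ignore_index=True)
    gm = pd.concat([r.gm_rows for r in results], ignore_index=True)

    # between-subject Pearson correlations, one per segment x scheme, + FDR
    rows = []
    for (segment, scheme), grp in gm.groupby(["segment", "scheme"]):
        if len(grp) < 4:
            continue
        res = parcel_stats.correlate_between_subjects(
            grp["gm_cbf"].to_numpy(), grp["gm_cvr"].to_numpy()
        )
        rows.append(
            {
                "segment": segment,
                "scheme": scheme,
                "r": res.full.r,
                "p": res.full.p,
                "r_screened": res.screened.r if res.screened else np.nan,
                "p_screened": res.screened.p if res.screened else np.nan,
                "n_removed": len(res.screened.removed_indices) if res.screened else 0,
            }
        )
    between = pd.DataFrame(rows)
    if len(between):
        between["p_fdr"] = parcel_stats.fdr_adjust(between["p"].to_numpy())

    # group inference on Fisher-Z spatial correlations (scheme x segment)
    cvr_spatial = spatial[spatial["metric"] == "cvr_amp"]
    design = group_inference.RmDesign.from_long(
        cvr_spatial, subject="subject", a="scheme", b="segment", value="fisher_z"
    )
    anova = group_inference.permute_rm_anova(
        design, n_perm=config.n_perm, seed=config.seed
    )
    screen = None
    if config.n_subjects >= 4:
        screen = group_inference.extreme_outlier_screen(
            design, n_perm=min(config.n_perm, 2000), seed=config.seed
        )
    pairwise = group_inference.simple_main_effects(
        design, factor="b", n_perm=min(config.n_perm, 10_000), seed=config.seed
    )

    recovery = pd.DataFrame(
        [
            {"subject": r.subject_id, "segment": seg, "scheme": scheme, **vals}
            for r in results
            for (seg, scheme), vals in r.recovery.items()
        ]
    )
    report = StudyReport(
        config=config,
        spatial=spatial,
        gm=gm,
        between=between,
        anova=anova,
        outlier_screen=screen,
        pairwise=pairwise,
        rsfc_spatial=spatial[spatial["metric"] != "cvr_amp"],
        recovery=recovery,
        n_subjects=config.n_subjects,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
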
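"""Shared I/O, configuration, smoothing and provenance utilities.

All volumes are NIfTI-1 handled through nibabel; voxel indexing is 0-based
everywhere internally and world coordinates exist only through the affine.
Tables are plain TSV and sidecar metadata is JSON, so every stage of the
pipeline can be rerun from files on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lagcvr")

__all__ = [
    "read_volume",
    "write_volume",
    "check_same_grid",
    "read_table",
    "write_table",
    "write_json",
    "masked_gaussian_smooth",
    "StudyConfig",
    "provenance",
]


# ---------------------------------------------------------------------------
# volumes


def read_volume(path):
    """Load a NIfTI volume, returning ``(data, affine)`` as float64."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(dtype=np.float64)), img.affine


def write_volume(path, data, affine=None):
    """Write ``data`` to a NIfTI-1 file (float64, lossless round trip)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
    return Path(path)


def check_same_grid(a_data, a_affine, b_data, b_affine, names=("a", "b"), atol=1e-6):
    """Raise ``ValueError`` naming both grids when companion files disagree."""
    if a_data.shape[:3] != b_data.shape[:3]:
        raise ValueError(
            f"grid mismatch: {names[0]} has shape {a_data.shape[:3]}, "
            f"{names[1]} has shape {b_data.shape[:3]}"
        )
    if not np.allclose(a_affine, b_affine, atol=atol):
        raise ValueError(
            f"affine mismatch between {names[0]} and {names[1]}:\n"
            f"{a_affine}\nvs\n{b_affine}"
        )


# ---------------------------------------------------------------------------
# tables / json


def read_table(path):
    return pd.read_csv(path, sep="\t")


def write_table(path, df):
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path, payload):
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
    return Path(path)


# ---------------------------------------------------------------------------
# smoothing (shared by asl_cbf and rsfc_metrics)


def masked_gaussian_smooth(data, fwhm_mm, voxel_mm=(2.0, 2.0, 2.0), mask=None):
    """Gaussian smoothing with mask-aware edge renormalization.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` in mm, converted to voxels
    via ``voxel_mm``.  Smoothing the masked data and dividing by the smoothed
    mask keeps a constant image constant inside the mask (no edge dimming).
    ``fwhm_mm == 0`` is the identity.
    """
    from scipy.ndimage import gaussian_filter

    data = np.asarray(data, dtype=np.float64)
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return data.copy()
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in np.broadcast_to(voxel_mm, (3,))]
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    num = gaussian_filter(np.where(mask, data, 0.0), sigma_vox)
    den = gaussian_filter(mask.astype(np.float64), sigma_vox)
    out = np.zeros_like(data)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    out[~mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Parameters governing a full simulated / analyzed study.

    Every field is echoed verbatim into the provenance block of each output.
    Unknown keys in a YAML/dict source are rejected so silent typos cannot
    change an analysis.
    """

    tr_s: float = 1.2
    lag_limit_s: float = 15.0
    lag_step_s: float = 0.3
    drift_seconds_per_order: float = 150.0
    gm_threshold: float = 0.5
    band_hz: tuple = (0.01, 0.1)
    fwhm_mm: float = 4.0
    n_perm: int = 100_000
    seed: int = 0
    n_subjects: int = 9
    grid_shape: tuple = (24, 24, 12)
    voxel_mm: float = 2.0
    n_regions: int = 48
    coupling_rho: float = 0.6
    tsnr: float = 50.0
    rest_duration_s: float = 480.0
    n_discard: int = 10
    out_dir: str | None = None
    asl_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("band_hz", "grid_shape"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self):
        return dataclasses.asdict(self)

    def config_hash(self):
        blob = json.dumps(self.to_dict(), sort_keys=True, default=_jsonable)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance(config=None, seed=None, stage=""):
    """Provenance block attached to every written output."""
    from lagcvr import __version__

    block = {"stage": stage, "software_version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        block["config"] = config.to_dict()
        block["config_hash"] = config.config_hash()
    return block
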
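"""Spatial smoothing and head-motion quality control.

The two preprocessing elements applied on the common analysis grid: Gaussian
spatial smoothing (default 6 mm FWHM) and the run-level motion exclusion rule
(more than one voxel of translation or 0.5 degrees of rotation relative to the
first volume, or too many outlier scans).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MOTION_COLUMNS, ConfoundSet, RunKey

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class QcLimits:
    """Motion-exclusion limits.

    translation_voxels: translation limit expressed in voxels (1 voxel by
    default, resolved against the run's own voxel size).
    rotation_deg: rotation limit in degrees.
    outlier_limit: a run with at least this many flagged outlier scans is
    excluded (mirrors the subject-exclusion rule for outlier regressors).
    """

    translation_voxels: float = 1.0
    rotation_deg: float = 0.5
    outlier_limit: int = 23


@dataclass
class QcDecision:
    run_id: RunKey | None
    max_translation_mm: np.ndarray
    max_rotation_deg: np.ndarray
    n_outlier_scans: int
    excluded: bool
    reason: str = ""


def motion_qc(
    confounds: ConfoundSet,
    voxel_size_mm: float | tuple[float, float, float] = 3.0,
    limits: QcLimits | None = None,
    run_id: RunKey | None = None,
) -> QcDecision:
    """Decide whether a run is excluded for excess head motion.

    Deviation of each motion trace is measured as the maximum absolute value
    after subtracting its first sample (the realignment reference volume).
    """
    limits = limits or QcLimits()
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    motion = confounds.motion
    if not np.isfinite(motion).all():
        return QcDecision(
            run_id=run_id,
            max_translation_mm=np.full(3, np.nan),
            max_rotation_deg=np.full(3, np.nan),
            n_outlier_scans=int(confounds.outlier_flags.sum()),
            excluded=True,
            reason="invalid confounds",
        )
    dev = np.abs(motion - motion[0]).max(axis=0)
    trans_dev, rot_dev = dev[:3], dev[3:]
    trans_limit = limits.translation_voxels * voxel
    n_out = int(confounds.outlier_flags.sum())

    excluded = False
    reason = ""
    if (trans_dev > trans_limit).any():
        ax = int(np.argmax(trans_dev - trans_limit))
        excluded, reason = True, (
            f"{MOTION_COLUMNS[ax]} deviation {trans_dev[ax]:.3f} mm exceeds "
            f"{trans_limit[ax]:.3f} mm ({limits.translation_voxels:g} voxel)"
        )
    elif (rot_dev > limits.rotation_deg).any():
        ax = int(np.argmax(rot_dev))
        excluded, reason = True, (
            f"{MOTION_COLUMNS[3 + ax]} deviation {rot_dev[ax]:.3f} deg exceeds "
            f"{limits.rotation_deg:g} deg"
        )
    elif n_out >= limits.outlier_limit:
        excluded, reason = True, f"outlier limit: {n_out} >= {limits.outlier_limit}"

    return QcDecision(
        run_id=run_id,
        max_translation_mm=trans_dev,
        max_rotation_deg=rot_dev,
        n_outlier_scans=n_out,
        excluded=excluded,
        reason=reason,
    )


def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | tuple[float, float, float],
) -> np.ndarray:
    """Separable Gaussian smoothing of a 3D volume or 4D run (volume-wise).

    sigma per axis is fwhm / (voxel_size * sqrt(8 ln 2)); boundary handling is
    symmetric (reflect) and the kernel is truncated at 4 sigma, which conserves
    the grid sum for interior-supported signal. fwhm_mm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim not in (3, 4):
        raise ValueError("expected a 3D volume or 4D run")
    if fwhm_mm == 0:
        return volume.copy()
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel
    if volume.ndim == 3:
        return ndimage.gaussian_filter(volume, sigma_vox, mode="reflect", truncate=4.0)
    sigma4 = np.append(sigma_vox, 0.0)  # never blur across time
    return ndimage.gaussian_filter(volume, sigma4, mode="reflect", truncate=4.0)
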
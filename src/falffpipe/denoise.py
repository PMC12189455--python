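"""Confound regression and band-pass filtering.

The nuisance model regresses 6 rigid-body motion parameters, their first
derivatives, one indicator column per flagged outlier scan, and the WM and CSF
mean-signal traces, plus an intercept. Band-pass filtering is an ideal
(rectangular) DFT-domain projection onto the 0.01-0.1 Hz bins; because it is an
orthogonal projection, the downstream fALFF ratio is guaranteed to lie in
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MOTION_COLUMNS, BoldRun, BrainMask, ConfoundSet, DenoisedRun

logger = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (0.01, 0.1)

#: Head radius (mm) used to convert rotations to arc displacement in the
#: framewise-displacement summary.
FD_ROTATION_RADIUS_MM = 50.0


class RunRejectedError(RuntimeError):
    """A run failed an inclusion rule (e.g. too many outlier scans)."""


@dataclass
class RegressorMatrix:
    """Nuisance design: t x k column matrix with labels."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def build_regressor_matrix(
    confounds: ConfoundSet, outlier_limit: int = 23
) -> RegressorMatrix:
    """Assemble intercept + motion + derivatives + outlier indicators + WM/CSF.

    Raises RunRejectedError when the number of flagged outlier scans reaches
    ``outlier_limit`` (the run-exclusion rule). Exact-duplicate and all-zero
    columns are dropped with a logged warning.
    """
    t = confounds.n_timepoints
    n_out = int(confounds.outlier_flags.sum())
    if n_out >= outlier_limit:
        raise RunRejectedError(
            f"outlier limit: {n_out} flagged scans >= {outlier_limit}"
        )

    cols: list[np.ndarray] = [np.ones(t)]
    labels: list[str] = ["intercept"]
    for i, name in enumerate(MOTION_COLUMNS):
        cols.append(confounds.motion[:, i])
        labels.append(name)
    deriv = confounds.motion_derivatives
    for i, name in enumerate(MOTION_COLUMNS):
        cols.append(deriv[:, i])
        labels.append(f"d_{name}")
    for scan in np.flatnonzero(confounds.outlier_flags):
        indicator = np.zeros(t)
        indicator[scan] = 1.0
        cols.append(indicator)
        labels.append(f"outlier_{scan}")
    if confounds.wm_trace is not None:
        cols.append(np.asarray(confounds.wm_trace, dtype=float))
        labels.append("wm")
    if confounds.csf_trace is not None:
        cols.append(np.asarray(confounds.csf_trace, dtype=float))
        labels.append("csf")

    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("regressor matrix contains non-finite values")

    # drop all-zero columns, then exact duplicates (keep first occurrence)
    keep = []
    seen: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if not col.any():
            logger.warning("dropping all-zero regressor column %r", labels[j])
            continue
        dup = next((i for i in seen if np.array_equal(X[:, i], col)), None)
        if dup is not None:
            logger.warning(
                "dropping duplicate regressor column %r (== %r)",
                labels[j],
                labels[dup],
            )
            continue
        seen.append(j)
        keep.append(j)
    return RegressorMatrix(values=X[:, keep], labels=[labels[j] for j in keep])


def framewise_displacement(
    motion: np.ndarray, rotation_radius_mm: float = FD_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Power-style FD: sum of absolute backward differences of the six traces,
    rotations converted to arc length on a sphere of the given radius."""
    d = np.diff(motion, axis=0, prepend=motion[:1])
    trans = np.abs(d[:, :3]).sum(axis=1)
    rot = np.abs(np.deg2rad(d[:, 3:])).sum(axis=1) * rotation_radius_mm
    return trans + rot


def detect_outlier_scans(
    run: BoldRun,
    confounds: ConfoundSet,
    mask: BrainMask | None = None,
    fd_threshold_mm: float = 0.9,
    global_z_threshold: float = 5.0,
) -> np.ndarray:
    """Flag outlier scans by framewise displacement or global-signal z-score.

    Flags are OR-combined with any flags already present in the confound set.
    """
    if run.n_timepoints != confounds.n_timepoints:
        raise ValueError("run and confounds have different lengths")
    fd = framewise_displacement(confounds.motion)
    flags = fd > fd_threshold_mm

    if mask is not None:
        voxels = run.data[mask.data]
    else:
        voxels = run.data.reshape(-1, run.n_timepoints)
    gs = voxels.mean(axis=0)
    sd = gs.std()
    if sd > 0:
        flags |= np.abs(gs - gs.mean()) / sd > global_z_threshold
    return flags | confounds.outlier_flags


def regress_confounds(
    run: BoldRun | np.ndarray, X: RegressorMatrix, mask: BrainMask | None = None
) -> np.ndarray:
    """Per-voxel ordinary least squares; returns the 4D residual grid.

    Residuals are orthogonal to every design column. Out-of-mask voxels are
    left at zero.
    """
    data = run.data if isinstance(run, BoldRun) else np.asarray(run, dtype=float)
    t = data.shape[-1]
    Xv = X.values
    if Xv.shape[0] != t:
        raise ValueError(f"design has {Xv.shape[0]} rows but run has {t} timepoints")
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify a minimal set of collinear columns for the error message
        bad = []
        kept: list[int] = []
        for j in range(Xv.shape[1]):
            if np.linalg.matrix_rank(Xv[:, kept + [j]]) == len(kept):
                bad.append(X.labels[j])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient regressor matrix; collinear columns: {bad}")

    if mask is not None:
        series = data[mask.data]  # (n_vox, t)
    else:
        series = data.reshape(-1, t)
    # QR projection: residual = Y - Q Q^T Y (fast and numerically stable)
    Q, _ = np.linalg.qr(Xv)
    resid = series - (Q @ (Q.T @ series.T)).T

    out = np.zeros_like(data)
    if mask is not None:
        out[mask.data] = resid
    else:
        out[...] = resid.reshape(data.shape)
    return out


def band_bin_indices(
    n_timepoints: int, tr_s: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Indices of the real-FFT bins retained by the ideal band-pass filter
    (frequencies f with f_lo <= f <= f_hi; DC is never retained)."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_s)
    keep = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    return np.flatnonzero(keep)


def bandpass(
    series: np.ndarray,
    tr_s: float,
    f_lo: float = DEFAULT_BAND_HZ[0],
    f_hi: float = DEFAULT_BAND_HZ[1],
) -> np.ndarray:
    """Ideal DFT-domain band-pass along the last axis.

    Bins with f_lo <= |f| <= f_hi are retained, everything else (including DC)
    is zeroed. The operation is an orthogonal projection, hence idempotent and
    energy-decreasing.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    if n < 16:
        raise ValueError("series must have at least 16 samples")
    nyquist = 0.5 / tr_s
    if not (0 <= f_lo < f_hi):
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"f_hi={f_hi} Hz exceeds Nyquist {nyquist} Hz")
    spec = np.fft.rfft(series, axis=-1)
    keep = band_bin_indices(n, tr_s, f_lo, f_hi)
    filt = np.zeros_like(spec)
    filt[..., keep] = spec[..., keep]
    return np.fft.irfft(filt, n=n, axis=-1)


def denoise_run(
    run: BoldRun,
    confounds: ConfoundSet,
    mask: BrainMask | None = None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    detect_outliers: bool = True,
    outlier_limit: int = 23,
) -> DenoisedRun:
    """Full denoising of one run: outlier detection, confound regression and
    band-pass filtering; returns the (unfiltered, filtered) residual pair."""
    if detect_outliers:
        flags = detect_outlier_scans(run, confounds, mask=mask)
        confounds = ConfoundSet(
            motion=confounds.motion,
            outlier_flags=flags,
            wm_trace=confounds.wm_trace,
            csf_trace=confounds.csf_trace,
        )
    X = build_regressor_matrix(confounds, outlier_limit=outlier_limit)
    resid = regress_confounds(run, X, mask=mask)
    # mean removal: with an intercept in the model residual means are already
    # ~0; subtract explicitly so the fALFF denominator is exactly DC-free
    if mask is not None:
        # air voxels are zero; filter in-mask series only
        r = resid[mask.data]
        r -= r.mean(axis=-1, keepdims=True)
        resid[mask.data] = r
        filtered = np.zeros(resid.shape)
        filtered[mask.data] = bandpass(r, run.tr_s, *band_hz)
    else:
        resid -= resid.mean(axis=-1, keepdims=True)
        filtered = bandpass(resid, run.tr_s, *band_hz)
    return DenoisedRun(
        residual_unfiltered=resid,
        residual_filtered=filtered,
        band_hz=tuple(band_hz),
        tr_s=run.tr_s,
        regressor_labels=X.labels,
        run_id=run.run_id,
    )
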
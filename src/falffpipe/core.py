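"""Shared data containers for the fALFF pipeline.

All volumes are numpy arrays in (x, y, z[, t]) order; world coordinates are
obtained through the NIfTI affine (RAS+ mm). Confound traces follow the
conventional 6-parameter rigid-body layout: three translations in mm, three
rotations in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Column order for rigid-body motion traces.
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class RunKey:
    """Identity of one BOLD run: subject x visit x scanning phase."""

    subject: str
    visit: str = "baseline"
    phase: str = "pre"

    def __str__(self) -> str:
        return f"{self.subject}/{self.visit}/{self.phase}"


@dataclass
class BoldRun:
    """One 4D BOLD run with its acquisition geometry.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensities, arbitrary units.
    tr_s : float
        Repetition time in seconds.
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Grid-to-world (mm) transform.
    run_id : RunKey
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    run_id: RunKey

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun.data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BoldRun needs at least 2 timepoints")
        if not np.isfinite(self.data).all():
            raise ValueError("BoldRun.data contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class BrainMask:
    """3D boolean analysis mask sharing grid and affine with its runs."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("BrainMask.data must be 3D")
        if not self.data.any():
            raise ValueError("BrainMask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ConfoundSet:
    """Per-run nuisance traces.

    motion : ndarray, shape (t, 6)
        Translations (mm) and rotations (deg), columns per MOTION_COLUMNS.
    outlier_flags : ndarray of bool, shape (t,)
    wm_trace, csf_trace : ndarray, shape (t,), optional
        Mean-signal traces from white matter and CSF.
    """

    motion: np.ndarray
    outlier_flags: np.ndarray | None = None
    wm_trace: np.ndarray | None = None
    csf_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=np.float64)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("ConfoundSet.motion must have shape (t, 6)")
        t = self.motion.shape[0]
        if self.outlier_flags is None:
            self.outlier_flags = np.zeros(t, dtype=bool)
        else:
            self.outlier_flags = np.asarray(self.outlier_flags).astype(bool)
        for name in ("outlier_flags", "wm_trace", "csf_trace"):
            trace = getattr(self, name)
            if trace is not None and len(trace) != t:
                raise ValueError(f"ConfoundSet.{name} length {len(trace)} != t={t}")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]

    @property
    def motion_derivatives(self) -> np.ndarray:
        """First differences of the motion traces; first sample is 0."""
        return np.diff(self.motion, axis=0, prepend=self.motion[:1])


@dataclass
class DenoisedRun:
    """Confound-regressed residual pair for one run.

    residual_unfiltered is mean-removed but not band-passed; residual_filtered
    is additionally restricted to the analysis band. The fALFF ratio is the
    RMS of the second over the RMS of the first.
    """

    residual_unfiltered: np.ndarray
    residual_filtered: np.ndarray
    band_hz: tuple[float, float]
    tr_s: float
    regressor_labels: list[str] = field(default_factory=list)
    run_id: RunKey | None = None

    def __post_init__(self) -> None:
        if self.residual_unfiltered.shape != self.residual_filtered.shape:
            raise ValueError("residual pair must share a shape")


DESIGN_COLUMNS = ("subject", "group", "visit", "phase", "age")


def validate_design(design) -> None:
    """Check that a cohort design table has the required columns."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if not np.isfinite(np.asarray(design["age"], dtype=float)).all():
        raise ValueError("design table has non-finite ages")
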
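"""Readers and writers: NIfTI-1 volumes, TSV confound/design tables, JSON
sidecars. Thin wrappers over nibabel and pandas that enforce the pipeline's
schemas."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DESIGN_COLUMNS, MOTION_COLUMNS, BoldRun, BrainMask, ConfoundSet, RunKey, validate_design

logger = logging.getLogger(__name__)


def read_bold(path: str | Path, tr_s: float | None = None, run_id: RunKey | None = None) -> BoldRun:
    """Load a 4D NIfTI run. TR is taken from the header; an explicit tr_s
    overrides it (with a logged warning on mismatch)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_s is not None:
        if header_tr and abs(header_tr - tr_s) > 1e-6:
            logger.warning(
                "%s: header TR %.3f s overridden by configured TR %.3f s",
                path, header_tr, tr_s,
            )
        tr = tr_s
    else:
        if header_tr <= 0:
            raise ValueError(f"{path}: no usable TR in header; pass tr_s")
        tr = header_tr
    zooms = img.header.get_zooms()[:3]
    return BoldRun(
        data=data,
        tr_s=tr,
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
        run_id=run_id or RunKey(Path(path).stem),
    )


def write_bold(run: BoldRun, path: str | Path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms((*run.voxel_size_mm, run.tr_s))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(data=np.asarray(img.get_fdata()) > 0.5, affine=np.asarray(img.affine))


def check_grid_match(run: BoldRun, mask: BrainMask, run_name: str = "run", mask_name: str = "mask") -> None:
    if run.grid_shape != mask.data.shape:
        raise ValueError(
            f"grid mismatch: {run_name} has shape {run.grid_shape} but "
            f"{mask_name} has shape {mask.data.shape}"
        )
    if not np.allclose(run.affine, mask.affine, atol=1e-4):
        raise ValueError(f"affine mismatch between {run_name} and {mask_name}")


def write_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D map (NaN allowed) as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


CONFOUND_COLUMNS = (*MOTION_COLUMNS, "outlier")


def read_confounds(path: str | Path) -> ConfoundSet:
    """Read a confound TSV (trans_x/y/z mm, rot_x/y/z deg, outlier 0/1 and
    optional wm / csf columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: confound table missing columns {missing}")
    motion = df.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    flags = (
        df["outlier"].to_numpy(dtype=float) > 0.5 if "outlier" in df.columns else None
    )
    wm = df["wm"].to_numpy(dtype=float) if "wm" in df.columns else None
    csf = df["csf"].to_numpy(dtype=float) if "csf" in df.columns else None
    return ConfoundSet(motion=motion, outlier_flags=flags, wm_trace=wm, csf_trace=csf)


def write_confounds(confounds: ConfoundSet, path: str | Path) -> None:
    df = pd.DataFrame(confounds.motion, columns=list(MOTION_COLUMNS))
    df["outlier"] = confounds.outlier_flags.astype(int)
    if confounds.wm_trace is not None:
        df["wm"] = confounds.wm_trace
    if confounds.csf_trace is not None:
        df["csf"] = confounds.csf_trace
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_design(df)
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.loc[:, list(DESIGN_COLUMNS)].to_csv(path, sep="\t", index=False)
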
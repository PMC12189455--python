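"""End-to-end orchestration: QC -> denoise -> fALFF -> normalize -> smooth ->
contrasts -> clusters -> tables.

The in-memory entry points (`process_run`, `analyze_cohort`) drive all
group-level analyses the study design supports: within-group phase contrasts
(during vs pre, paired by subject), the MS visit contrast (follow-up vs
baseline, paired, per phase), and the between-group contrast at baseline
(age-adjusted). `run_pipeline` wraps the same operations around on-disk
NIfTI/TSV inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import PipelineConfig
from .core import BoldRun, BrainMask, ConfoundSet, RunKey
from .denoise import bandpass, denoise_run

from .falff import compute_falff, rank_inverse_normal
from .inference import (
    ClusterResult,
    Contrast,
    SmoothnessEstimate,
    StatMap,
    fit_voxelwise_contrast,
    run_cluster_inference,
)
from .preprocess import QcDecision, QcLimits, motion_qc, smooth_gaussian
from .report import ClusterTableRow, SectionTotals, build_cluster_table, table_to_frame
from .synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass
class RunRecord:
    """Per-run provenance: QC outcome, regressor labels, undefined voxels."""

    run_id: RunKey
    qc: QcDecision
    regressor_labels: list[str] = field(default_factory=list)
    n_undefined_voxels: int = 0


@dataclass
class ContrastResult:
    contrast: Contrast
    stat: StatMap
    clusters: list[ClusterResult]
    smoothness: SmoothnessEstimate
    table_rows: list[ClusterTableRow]
    totals: SectionTotals


@dataclass
class PipelineResult:
    maps: dict[RunKey, np.ndarray]
    design: pd.DataFrame
    records: list[RunRecord]
    contrasts: dict[str, ContrastResult]
    mask: BrainMask


def process_run(
    run: BoldRun,
    confounds: ConfoundSet,
    mask: BrainMask,
    cfg: PipelineConfig | None = None,
) -> tuple[np.ndarray | None, RunRecord]:
    """QC, denoise, fALFF, normalize and smooth one run.

    Returns (map, record); the map is None when QC excludes the run.
    """
    cfg = cfg or PipelineConfig()
    limits = QcLimits(
        translation_voxels=cfg.qc_translation_voxels,
        rotation_deg=cfg.qc_rotation_deg,
        outlier_limit=cfg.outlier_limit,
    )
    qc = motion_qc(confounds, run.voxel_size_mm, limits, run_id=run.run_id)
    record = RunRecord(run_id=run.run_id, qc=qc)
    if qc.excluded:
        logger.info("run %s excluded: %s", run.run_id, qc.reason)
        return None, record

    denoised = denoise_run(
        run,
        confounds,
        mask=mask,
        band_hz=cfg.band_hz,
        outlier_limit=cfg.outlier_limit,
    )
    if cfg.falff_denominator == "raw":
        raw = run.data - run.data.mean(axis=-1, keepdims=True)
        denoised.residual_unfiltered = raw
        denoised.residual_filtered = bandpass(raw, run.tr_s, *cfg.band_hz)
    record.regressor_labels = denoised.regressor_labels

    fmap = compute_falff(denoised, mask)
    record.n_undefined_voxels = mask.n_voxels - fmap.n_defined
    if cfg.smoothing_target == "falff" and cfg.smoothing_fwhm_mm > 0:
        smoothed = np.where(fmap.defined, fmap.data, 0.0)
        fmap.data = np.where(
            fmap.defined,
            smooth_gaussian(smoothed, cfg.smoothing_fwhm_mm, run.voxel_size_mm),
            np.nan,
        )
    nmap = rank_inverse_normal(fmap)
    out = np.where(nmap.defined, nmap.data, 0.0)
    if cfg.smoothing_target == "normalized" and cfg.smoothing_fwhm_mm > 0:
        out = smooth_gaussian(out, cfg.smoothing_fwhm_mm, run.voxel_size_mm)
    return out, record


def standard_contrasts(design: pd.DataFrame) -> dict[str, tuple[Contrast, pd.Series]]:
    """The study's contrast battery, restricted to what the design supports.

    Returns {name: (contrast, row_selector)} where row_selector is a boolean
    Series over design rows.
    """
    out: dict[str, tuple[Contrast, pd.Series]] = {}
    for group in sorted(design["group"].unique()):
        for visit in sorted(design.loc[design["group"] == group, "visit"].unique()):
            sel = (design["group"] == group) & (design["visit"] == visit)
            phases = set(design.loc[sel, "phase"])
            if {"pre", "during"} <= phases:
                name = f"{group.lower()}_{visit}_phase"
                out[name] = (
                    Contrast(kind="paired", label=name, condition_col="phase",
                             condition_a="during", condition_b="pre"),
                    sel,
                )
    # visit contrast per phase, within subjects seen at both visits
    for group in sorted(design["group"].unique()):
        gsel = design["group"] == group
        visits = set(design.loc[gsel, "visit"])
        if {"baseline", "followup"} <= visits:
            for phase in ("pre", "during"):
                sel = gsel & (design["phase"] == phase)
                name = f"{group.lower()}_visit_{phase}"
                out[name] = (
                    Contrast(kind="paired", label=name, condition_col="visit",
                             condition_a="followup", condition_b="baseline"),
                    sel,
                )
    # between-group at baseline, age-adjusted, per phase
    if design["group"].nunique() >= 2:
        groups = sorted(design["group"].unique())
        for phase in ("pre", "during"):
            sel = (design["visit"] == "baseline") & (design["phase"] == phase)
            name = f"group_{phase}"
            out[name] = (
                Contrast(kind="two_sample", label=name, group_col="group",
                         group_a=groups[0], group_b=groups[1], covariates=("age",)),
                sel,
            )
    return out


def _condition_maps(
    maps: np.ndarray, design: pd.DataFrame, contrast: Contrast
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-subject (or per-group-member) maps for conditions A and B of a
    contrast, for cluster-table means. Condition A is the reference (pre /
    baseline / first group)."""
    design = design.reset_index(drop=True)
    if contrast.kind == "paired":
        col = contrast.condition_col
        a = [maps[i] for i in design.index[design[col] == contrast.condition_b]]
        b = [maps[i] for i in design.index[design[col] == contrast.condition_a]]
        return a, b
    a = [maps[i] for i in design.index[design[contrast.group_col] == contrast.group_a]]
    b = [maps[i] for i in design.index[design[contrast.group_col] == contrast.group_b]]
    return a, b


def analyze_contrast(
    maps: np.ndarray,
    design: pd.DataFrame,
    contrast: Contrast,
    mask: BrainMask,
    cfg: PipelineConfig,
    affine: np.ndarray | None = None,
    voxel_size_mm: float | tuple[float, float, float] = 3.0,
    atlas: np.ndarray | None = None,
    atlas_label_names: dict[int, str] | None = None,
) -> ContrastResult:
    """Fit one contrast and produce clusters plus its report table."""
    stat = fit_voxelwise_contrast(maps, design, contrast, mask)
    clusters, smoothness = run_cluster_inference(
        stat,
        mask,
        voxel_size_mm=voxel_size_mm,
        voxel_p=cfg.voxel_p,
        connectivity=cfg.connectivity,
        affine=affine,
        pool_signs=cfg.fdr_pool_signs,
    )
    significant = [c for c in clusters if c.p_fdr is not None and c.p_fdr < cfg.cluster_fdr]
    maps_a, maps_b = _condition_maps(maps, design, contrast)
    rows, totals = build_cluster_table(
        significant, maps_a, maps_b,
        atlas=atlas, atlas_label_names=atlas_label_names,
        grid_shape=mask.data.shape,
    )
    return ContrastResult(
        contrast=contrast, stat=stat, clusters=clusters,
        smoothness=smoothness, table_rows=rows, totals=totals,
    )


def analyze_cohort(
    runs: dict[RunKey, BoldRun] | Cohort,
    confounds: dict[RunKey, ConfoundSet] | None = None,
    design: pd.DataFrame | None = None,
    mask: BrainMask | None = None,
    cfg: PipelineConfig | None = None,
    contrasts: dict[str, tuple[Contrast, pd.Series]] | None = None,
) -> PipelineResult:
    """Run the full pipeline on an in-memory cohort."""
    if isinstance(runs, Cohort):
        cohort = runs
        runs, confounds, design, mask = (
            cohort.runs, cohort.confounds, cohort.design, cohort.mask,
        )
    assert confounds is not None and design is not None and mask is not None
    cfg = cfg or PipelineConfig()
    cfg.validate()

    maps: dict[RunKey, np.ndarray] = {}
    records: list[RunRecord] = []
    for _, row in design.iterrows():
        key = RunKey(row["subject"], row["visit"], row["phase"])
        m, record = process_run(runs[key], confounds[key], mask, cfg)
        records.append(record)
        if m is not None:
            maps[key] = m

    kept = design[
        [RunKey(r["subject"], r["visit"], r["phase"]) in maps for _, r in design.iterrows()]
    ].reset_index(drop=True)
    if kept.empty:
        raise RuntimeError("QC excluded every run; nothing to analyze")
    # drop incomplete pairs subject-wise later per contrast; stack in design order
    stack = np.stack(
        [maps[RunKey(r["subject"], r["visit"], r["phase"])] for _, r in kept.iterrows()]
    )

    voxel_size = next(iter(runs.values())).voxel_size_mm
    affine = next(iter(runs.values())).affine
    results: dict[str, ContrastResult] = {}
    for name, (contrast, sel_full) in (contrasts or standard_contrasts(kept)).items():
        sel = sel_full.reset_index(drop=True) if hasattr(sel_full, "reset_index") else sel_full
        sub_design = kept[sel].reset_index(drop=True)
        sub_maps = stack[np.asarray(sel)]
        # keep only subjects with complete pairs for paired contrasts
        if contrast.kind == "paired":
            col = contrast.condition_col
            counts = sub_design.groupby("subject")[col].nunique()
            complete = set(counts[counts == 2].index)
            keep_rows = sub_design["subject"].isin(complete).to_numpy()
            sub_design = sub_design[keep_rows].reset_index(drop=True)
            sub_maps = sub_maps[keep_rows]
            if sub_design["subject"].nunique() < 2:
                logger.info("skipping contrast %s: fewer than 2 complete pairs", name)
                continue
        results[name] = analyze_contrast(
            sub_maps, sub_design, contrast, mask, cfg,
            affine=affine, voxel_size_mm=voxel_size,
        )
    return PipelineResult(
        maps=maps, design=kept, records=records, contrasts=results, mask=mask
    )


# ---------------------------------------------------------------------------
# on-disk pipeline


def _run_paths(cfg: PipelineConfig, design: pd.DataFrame):
    runs_dir = Path(cfg.runs_dir)
    conf_dir = Path(cfg.confounds_dir or cfg.runs_dir)
    for _, row in design.iterrows():
        key = RunKey(row["subject"], row["visit"], row["phase"])
        stem = f"{key.subject}_{key.visit}_{key.phase}"
        yield key, runs_dir / f"{stem}_bold.nii.gz", conf_dir / f"{stem}_confounds.tsv"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a synthetic cohort as NIfTI runs + TSV confounds/design + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, run in cohort.runs.items():
        stem = f"{key.subject}_{key.visit}_{key.phase}"
        fio.write_bold(run, out / f"{stem}_bold.nii.gz")
        fio.write_confounds(cohort.confounds[key], out / f"{stem}_confounds.tsv")
    fio.write_design(cohort.design, out / "design.tsv")
    fio.write_map(
        cohort.mask.data.astype(np.float32), cohort.mask.affine, out / "mask.nii.gz"
    )
    for (group, phase), scale in cohort.truth.items():
        fio.write_map(scale, cohort.mask.affine, out / f"truth_{group}_{phase}.nii.gz")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the pipeline on on-disk inputs and write the output tree."""
    cfg.validate()
    for name in ("runs_dir", "design_path", "mask_path", "output_dir"):
        if getattr(cfg, name) is None:
            raise ValueError(f"config is missing required path: {name}")
    design = fio.read_design(cfg.design_path)
    mask = fio.read_mask(cfg.mask_path)

    runs: dict[RunKey, BoldRun] = {}
    confounds: dict[RunKey, ConfoundSet] = {}
    for key, bold_path, conf_path in _run_paths(cfg, design):
        run = fio.read_bold(bold_path, tr_s=cfg.tr_s, run_id=key)
        fio.check_grid_match(run, mask, run_name=str(bold_path), mask_name=str(cfg.mask_path))
        runs[key] = run
        confounds[key] = fio.read_confounds(conf_path)

    result = analyze_cohort(runs, confounds, design, mask, cfg)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = mask.affine
    qc_rows = []
    for rec in result.records:
        qc_rows.append(
            {
                "run": str(rec.run_id),
                "excluded": rec.qc.excluded,
                "reason": rec.qc.reason,
                "max_trans_mm": float(np.nanmax(rec.qc.max_translation_mm)),
                "max_rot_deg": float(np.nanmax(rec.qc.max_rotation_deg)),
                "n_outlier_scans": rec.qc.n_outlier_scans,
                "n_undefined_voxels": rec.n_undefined_voxels,
            }
        )
    pd.DataFrame(qc_rows).to_csv(out / "qc_log.tsv", sep="\t", index=False)

    for key, m in result.maps.items():
        fio.write_map(m, affine, out / f"{key.subject}_{key.visit}_{key.phase}_falffz.nii.gz")

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_runs_in": len(result.records),
        "n_runs_kept": len(result.maps),
        "contrasts": {},
    }
    for name, cres in result.contrasts.items():
        fio.write_map(cres.stat.t_values, affine, out / f"tmap_{name}.nii.gz")
        frame = table_to_frame(cres.table_rows)
        frame.to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
        manifest["contrasts"][name] = {
            "df": cres.stat.df,
            "df_unadjusted": cres.stat.df_unadjusted,
            "fwhm_mm": [float(v) for v in cres.smoothness.fwhm_mm],
            "resels": float(cres.smoothness.resels),
            "totals": dataclasses.asdict(cres.totals),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
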
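"""Cluster tables: per-cluster condition means, percentage-change formulas,
region labels and section totals.

The percentage change between two condition means a (reference) and b is
computed on the absolute values, ((|b| - |a|) / (|b| + |a|)) * 100, which is
bounded in [-100, 100] and invariant to positive rescaling of both inputs.
The same formula serves the between-group "relative difference". Both the
signed value and its magnitude are stored; rendering either is a table-style
choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import ClusterResult

logger = logging.getLogger(__name__)


def percentage_change(pre_mean: float, dur_mean: float) -> float:
    """Signed percentage change ((|dur| - |pre|) / (|dur| + |pre|)) * 100.

    Returns NaN (undefined) when both inputs are zero.
    """
    a, b = abs(pre_mean), abs(dur_mean)
    if a + b == 0:
        return float("nan")
    return (b - a) / (b + a) * 100.0


def relative_difference(hc_mean: float, ms_mean: float) -> float:
    """Signed relative difference ((|MS| - |HC|) / (|MS| + |HC|)) * 100.

    Which group is actually greater follows the contrast t-statistic's sign;
    this formula compares magnitudes only. NaN when both inputs are zero.
    """
    return percentage_change(hc_mean, ms_mean)


@dataclass
class ClusterTableRow:
    size_voxels: int
    sign: str
    peak_coordinate_mm: tuple[float, float, float] | None
    mean_a: float
    mean_b: float
    pct_change_signed: float
    pct_change_magnitude: float
    t_stat: float
    p_fdr: float | None
    regions: list[str] = field(default_factory=list)
    undefined_change: bool = False


@dataclass
class SectionTotals:
    n_clusters_increase: int
    voxels_increase: int
    n_clusters_decrease: int
    voxels_decrease: int


def section_totals(rows: list[ClusterTableRow]) -> SectionTotals:
    """Exact integer totals per sign over the table rows."""
    inc = [r for r in rows if r.sign == "increase"]
    dec = [r for r in rows if r.sign == "decrease"]
    return SectionTotals(
        n_clusters_increase=len(inc),
        voxels_increase=sum(r.size_voxels for r in inc),
        n_clusters_decrease=len(dec),
        voxels_decrease=sum(r.size_voxels for r in dec),
    )


def _cluster_condition_mean(
    cluster: ClusterResult, maps: list[np.ndarray] | np.ndarray
) -> float:
    """Mean map value over the cluster's voxels, first per subject then across
    subjects."""
    idx = cluster.voxel_indices
    per_subject = [float(np.nanmean(m[idx])) for m in maps]
    return float(np.mean(per_subject))


def _atlas_labels_for(
    cluster: ClusterResult,
    atlas: np.ndarray,
    label_names: dict[int, str],
    min_fraction: float = 0.10,
) -> list[str]:
    """Majority label plus any label covering >= min_fraction of the cluster."""
    vals = atlas[cluster.voxel_indices].astype(int)
    vals = vals[vals > 0]
    if vals.size == 0:
        return []
    counts = pd.Series(vals).value_counts()
    majority = int(counts.index[0])
    chosen = [majority] + [
        int(k) for k in counts.index[1:] if counts[k] / len(vals) >= min_fraction
    ]
    return [label_names.get(k, f"label_{k}") for k in chosen]


def build_cluster_table(
    clusters: list[ClusterResult],
    maps_a: list[np.ndarray] | np.ndarray,
    maps_b: list[np.ndarray] | np.ndarray,
    atlas: np.ndarray | None = None,
    atlas_label_names: dict[int, str] | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> tuple[list[ClusterTableRow], SectionTotals]:
    """Build paper-style rows for the clusters of one contrast.

    maps_a / maps_b: per-subject 3D maps for conditions A (reference, e.g.
    pre) and B (e.g. during). Cluster means are computed per subject over the
    cluster voxels, then averaged across subjects. Rows are sorted by size,
    descending, within sign (increases first).
    """
    if atlas is not None and grid_shape is not None and atlas.shape != tuple(grid_shape):
        logger.warning("atlas grid %s does not match analysis grid %s; labels omitted",
                       atlas.shape, tuple(grid_shape))
        atlas = None

    rows = []
    for c in clusters:
        mean_a = _cluster_condition_mean(c, maps_a)
        mean_b = _cluster_condition_mean(c, maps_b)
        pct = percentage_change(mean_a, mean_b)
        rows.append(
            ClusterTableRow(
                size_voxels=c.size_voxels,
                sign=c.sign,
                peak_coordinate_mm=(
                    tuple(np.round(c.peak_coordinate_mm, 3))
                    if c.peak_coordinate_mm is not None
                    else None
                ),
                mean_a=mean_a,
                mean_b=mean_b,
                pct_change_signed=pct,
                pct_change_magnitude=abs(pct),
                t_stat=c.peak_t,
                p_fdr=c.p_fdr,
                regions=(
                    _atlas_labels_for(c, atlas, atlas_label_names or {})
                    if atlas is not None
                    else []
                ),
                undefined_change=bool(np.isnan(pct)),
            )
        )
    sign_order = {"increase": 0, "decrease": 1}
    rows.sort(key=lambda r: (sign_order.get(r.sign, 2), -r.size_voxels))
    return rows, section_totals(rows)


def table_to_frame(rows: list[ClusterTableRow]) -> pd.DataFrame:
    """Render rows as a DataFrame mirroring the published column order."""
    return pd.DataFrame(
        {
            "Main Brain Regions": ["; ".join(r.regions) for r in rows],
            "Coordinates (x, y, z)": [
                r.peak_coordinate_mm if r.peak_coordinate_mm else "" for r in rows
            ],
            "Voxels": [r.size_voxels for r in rows],
            "Mean A (a.u.)": [r.mean_a for r in rows],
            "Mean B (a.u.)": [r.mean_b for r in rows],
            "Percentage Change (%)": [r.pct_change_signed for r in rows],
            "T-Stat": [r.t_stat for r in rows],
            "P-FDR": [r.p_fdr for r in rows],
            "Direction": [r.sign for r in rows],
        }
    )
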
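"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF at a voxel is the RMS of the band-passed (0.01-0.1 Hz) denoised signal
divided by the RMS of the same denoised, mean-removed signal before band-pass
filtering. With an ideal DFT band-pass this ratio is the square root of the
in-band fraction of the signal's nonzero-frequency power, so it lies in
[0, 1]. Maps are then standardized per run by a rank-based inverse-normal
transform: in-mask values are replaced by standard-normal quantiles of their
plotting positions (r - 0.5)/N, yielding a zero-mean, unit-variance map whose
rank order matches the source map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BrainMask, DenoisedRun, RunKey


@dataclass
class FalffMap:
    """Per-run 3D fALFF ratio map. Undefined voxels (zero denominator or
    outside the mask) are NaN; `defined` marks in-mask voxels with a valid
    ratio."""

    data: np.ndarray
    defined: np.ndarray
    band_hz: tuple[float, float]
    run_id: RunKey | None = None

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


@dataclass
class NormalizedFalffMap:
    """Rank inverse-normal standardized fALFF map (z-like units)."""

    data: np.ndarray
    defined: np.ndarray
    run_id: RunKey | None = None


def compute_falff(denoised: DenoisedRun, mask: BrainMask) -> FalffMap:
    """Compute the per-voxel fALFF ratio over the mask.

    Voxels whose unfiltered residual has zero RMS are flagged undefined.
    Raises if no in-mask voxel has signal (degenerate run).
    """
    if denoised.residual_unfiltered.shape[:3] != mask.data.shape:
        raise ValueError("denoised run and mask shapes disagree")
    num = np.sqrt(np.mean(denoised.residual_filtered[mask.data] ** 2, axis=-1))
    den = np.sqrt(np.mean(denoised.residual_unfiltered[mask.data] ** 2, axis=-1))

    data = np.full(mask.data.shape, np.nan)
    defined = np.zeros(mask.data.shape, dtype=bool)
    defined[mask.data] = den > 0
    if not defined.any():
        raise ValueError("degenerate run: all in-mask voxels have zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    data[mask.data] = ratio
    return FalffMap(
        data=data, defined=defined, band_hz=denoised.band_hz, run_id=denoised.run_id
    )


def rank_inverse_normal(fmap: FalffMap, mask: BrainMask | None = None) -> NormalizedFalffMap:
    """Rank-based inverse-normal standardization of one fALFF map.

    Applied independently per run (per subject and session). Ties receive
    average ranks; N counts defined in-mask voxels only.
    """
    defined = fmap.defined if mask is None else (fmap.defined & mask.data)
    values = fmap.data[defined]
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 defined in-mask voxels")
    if np.all(values == values[0]):
        raise ValueError("non-informative map: all defined voxels are tied")
    ranks = stats.rankdata(values, method="average")
    z = stats.norm.ppf((ranks - 0.5) / n)
    out = np.full(fmap.data.shape, np.nan)
    out[defined] = z
    return NormalizedFalffMap(data=out, defined=defined, run_id=fmap.run_id)
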
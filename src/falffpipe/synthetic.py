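"""Synthetic multi-subject BOLD cohort generator.

Emulates the study design the pipeline was built for: two groups (28 healthy
controls with one visit, 20 MS patients with baseline and follow-up visits),
two scanning phases per visit (pre / during stimulation), 153 timepoints at
TR = 2 s on a 3 mm isotropic grid (64 x 64 x 35 by default, an ellipsoidal
"brain" of baseline intensity 1000 inside the field of view).

Each in-mask voxel's series is

    baseline + linear drift + scale * band-limited component + AR(1) noise

where the band-limited component is synthesized on the DFT bins inside the
0.01-0.1 Hz analysis band with random phases and a deterministic amplitude
profile, so that planted amplitude scales translate exactly into in-band
spectral power ratios of scale^2. Effect regions multiply the in-band
component by a phase-dependent and/or group-dependent factor, giving a known
ground-truth fALFF perturbation for recovery tests.

Motion traces are smoothed random walks emitted as confounds only; volumes are
never resampled (the cohort is generated pre-aligned). Flagged outlier scans
receive a global intensity spike so that data-driven outlier detection has
something to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import BoldRun, BrainMask, ConfoundSet, RunKey
from .denoise import band_bin_indices

BASELINE_INTENSITY = 1000.0


@dataclass(frozen=True)
class NoiseModel:
    """Per-voxel noise parameters (arbitrary intensity units).

    ar1_coefficient: lag-1 coefficient of the broadband noise, in [0, 1).
    in_band_sigma: standard deviation of the band-limited (0.01-0.1 Hz)
        component at scale 1.
    broadband_sigma: marginal standard deviation of the AR(1) broadband noise.
    drift_amplitude: standard deviation of the per-voxel linear drift total
        excursion over a run.
    motion_sigma: RMS scale of the simulated motion traces (mm for
        translations, degrees for rotations).
    outlier_rate: per-scan probability of an outlier.
    """

    ar1_coefficient: float = 0.3
    in_band_sigma: float = 1.0
    broadband_sigma: float = 1.0
    drift_amplitude: float = 1.0
    motion_sigma: float = 0.1
    outlier_rate: float = 0.02

    def validate(self) -> None:
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        for name in ("in_band_sigma", "broadband_sigma", "drift_amplitude", "motion_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")


@dataclass(frozen=True)
class EffectRoi:
    """A set of voxels whose in-band amplitude is scaled.

    phase_scale multiplies the in-band component in the "during" phase
    relative to "pre" (> 1 plants an fALFF increase); group_scale is the
    analogous factor applied to the MS group (both phases).
    """

    voxels: tuple[tuple[int, int, int], ...]
    phase_scale: float = 1.0
    group_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.voxels) == 0:
            raise ValueError("EffectRoi.voxels must be nonempty")
        if self.phase_scale <= 0 or self.group_scale <= 0:
            raise ValueError("EffectRoi scales must be > 0")

    @classmethod
    def ball(
        cls,
        center: tuple[int, int, int],
        n_voxels: int,
        grid_shape: tuple[int, int, int],
        phase_scale: float = 1.0,
        group_scale: float = 1.0,
    ) -> "EffectRoi":
        """The n_voxels grid points closest to `center` (a quasi-spherical
        region; ties broken by grid order)."""
        idx = np.indices(grid_shape).reshape(3, -1).T
        d2 = ((idx - np.asarray(center)) ** 2).sum(axis=1)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
        chosen = idx[order[:n_voxels]]
        return cls(
            voxels=tuple(map(tuple, chosen.tolist())),
            phase_scale=phase_scale,
            group_scale=group_scale,
        )


@dataclass
class SyntheticSpec:
    """Full description of a simulated cohort."""

    grid_shape: tuple[int, int, int] = (64, 64, 35)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 153
    tr_s: float = 2.0
    n_hc: int = 28
    n_ms: int = 20
    hc_age_range: tuple[float, float] = (20.0, 65.0)
    ms_age_range: tuple[float, float] = (25.0, 70.0)
    band_hz: tuple[float, float] = (0.01, 0.1)
    effect_rois: list[EffectRoi] = field(default_factory=list)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be >= 16")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape entries must all be >= 4")
        if self.n_hc < 0 or self.n_ms < 0:
            raise ValueError("group sizes must be >= 0")
        self.noise.validate()
        for roi in self.effect_rois:
            for v in roi.voxels:
                if any(not 0 <= v[i] < self.grid_shape[i] for i in range(3)):
                    raise ValueError(f"effect_rois voxel {v} outside grid {self.grid_shape}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        # center the grid on the world origin, RAS+
        aff[:3, 3] = -0.5 * (np.asarray(self.grid_shape) - 1) * self.voxel_size_mm
        return aff


def ellipsoid_mask(spec: SyntheticSpec) -> BrainMask:
    """Ellipsoidal brain mask inscribed in the grid (semi-axes 0.45 * shape)."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.45 * shape
    idx = np.indices(spec.grid_shape)
    r2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return BrainMask(data=r2 <= 1.0, affine=spec.affine)


def effect_scale_map(
    spec: SyntheticSpec, group: str, phase: str
) -> np.ndarray:
    """Ground-truth in-band amplitude scale per voxel for one group x phase."""
    scale = np.ones(spec.grid_shape)
    for roi in spec.effect_rois:
        s = 1.0
        if phase == "during":
            s *= roi.phase_scale
        if group == "MS":
            s *= roi.group_scale
        for v in roi.voxels:
            scale[v] *= s
    return scale


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], a: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis."""
    e = rng.standard_normal(shape)
    if a == 0:
        return e
    # innovations scaled for a stationary start: x0 ~ N(0,1) exactly
    w = e * np.sqrt(1 - a**2)
    w[..., 0] = e[..., 0]
    return signal.lfilter([1.0], [1.0, -a], w, axis=-1)


def _motion_traces(rng: np.random.Generator, t: int, sigma: float) -> np.ndarray:
    """Six smoothed-random-walk traces, zero at the first sample, unit RMS
    shape scaled by sigma."""
    steps = _ar1(rng, (6, t), 0.5)
    walk = np.cumsum(steps, axis=1)
    walk -= walk[:, :1]
    rms = np.sqrt((walk**2).mean(axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return (sigma * walk / rms).T


def synthesize_run(
    spec: SyntheticSpec,
    scale_map: np.ndarray,
    seed: int | np.random.SeedSequence,
    run_id: RunKey | None = None,
    mask: BrainMask | None = None,
) -> tuple[BoldRun, ConfoundSet]:
    """Generate one BOLD run and its confounds.

    scale_map multiplies the in-band component voxelwise. Only in-mask voxels
    carry signal; the rest of the grid is zero (air).
    """
    spec.validate()
    scale_map = np.asarray(scale_map, dtype=float)
    if scale_map.shape != tuple(spec.grid_shape):
        raise ValueError("scale_map not aligned to grid")
    if not np.isfinite(scale_map).all():
        raise ValueError("scale_map contains non-finite values")
    mask = mask or ellipsoid_mask(spec)
    rng = np.random.default_rng(seed)
    t = spec.n_timepoints
    nz = spec.noise
    mvox = mask.data
    n_vox = int(mvox.sum())

    # band-limited component: fixed amplitude per retained bin, random phases
    bins = band_bin_indices(t, spec.tr_s, *spec.band_hz)
    m_bins = len(bins)
    series = np.zeros((n_vox, t))
    if m_bins and nz.in_band_sigma > 0:
        amp = nz.in_band_sigma * np.sqrt(2.0 / m_bins)
        phases = rng.uniform(0, 2 * np.pi, size=(n_vox, m_bins))
        spec_arr = np.zeros((n_vox, t // 2 + 1), dtype=complex)
        spec_arr[:, bins] = (t / 2.0) * amp * np.exp(1j * phases)
        series = np.fft.irfft(spec_arr, n=t, axis=1)
    series *= scale_map[mvox][:, None]

    if nz.broadband_sigma > 0:
        series += nz.broadband_sigma * _ar1(rng, (n_vox, t), nz.ar1_coefficient)
    if nz.drift_amplitude > 0:
        slopes = rng.normal(0.0, nz.drift_amplitude, size=n_vox)
        ramp = np.linspace(-0.5, 0.5, t)
        series += slopes[:, None] * ramp[None, :]
    series += BASELINE_INTENSITY

    motion = _motion_traces(rng, t, nz.motion_sigma)
    flags = rng.random(t) < nz.outlier_rate
    if flags.any():
        # global spike so data-driven detection can see flagged scans
        series[:, flags] += 8.0 * max(nz.broadband_sigma, 1e-3)

    wm = _ar1(rng, (t,), 0.5)
    csf = _ar1(rng, (t,), 0.5)

    data = np.zeros(spec.grid_shape + (t,))
    data[mvox] = series
    run = BoldRun(
        data=data,
        tr_s=spec.tr_s,
        voxel_size_mm=(spec.voxel_size_mm,) * 3,
        affine=spec.affine,
        run_id=run_id or RunKey("synthetic"),
    )
    confounds = ConfoundSet(
        motion=motion, outlier_flags=flags, wm_trace=wm, csf_trace=csf
    )
    return run, confounds


@dataclass
class Cohort:
    """A generated cohort: runs with confounds, the design table, the shared
    brain mask and the ground-truth amplitude scale maps per group x phase."""

    runs: dict[RunKey, BoldRun]
    confounds: dict[RunKey, ConfoundSet]
    design: pd.DataFrame
    mask: BrainMask
    truth: dict[tuple[str, str], np.ndarray]
    spec: SyntheticSpec


def _cohort_layout(spec: SyntheticSpec) -> list[tuple[str, str, str, str]]:
    """(subject, group, visit, phase) rows in deterministic order. HC have one
    visit, MS have two; every visit has both phases."""
    rows = []
    for i in range(spec.n_hc):
        subj = f"HC{i + 1:02d}"
        for phase in ("pre", "during"):
            rows.append((subj, "HC", "baseline", phase))
    for i in range(spec.n_ms):
        subj = f"MS{i + 1:02d}"
        for visit in ("baseline", "followup"):
            for phase in ("pre", "during"):
                rows.append((subj, "MS", visit, phase))
    return rows


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Generate the full cohort deterministically from spec.seed."""
    spec.validate()
    mask = ellipsoid_mask(spec)
    layout = _cohort_layout(spec)

    root = np.random.SeedSequence(spec.seed)
    age_seed, *run_seeds = root.spawn(len(layout) + 1)
    age_rng = np.random.default_rng(age_seed)
    subjects: dict[str, tuple[str, float]] = {}
    for subj, group, _, _ in layout:
        if subj not in subjects:
            lo, hi = spec.hc_age_range if group == "HC" else spec.ms_age_range
            subjects[subj] = (group, float(age_rng.uniform(lo, hi)))

    truth = {
        (g, p): effect_scale_map(spec, g, p)
        for g in ("HC", "MS")
        for p in ("pre", "during")
    }

    runs: dict[RunKey, BoldRun] = {}
    confounds: dict[RunKey, ConfoundSet] = {}
    records = []
    for (subj, group, visit, phase), seed in zip(layout, run_seeds):
        key = RunKey(subject=subj, visit=visit, phase=phase)
        run, conf = synthesize_run(
            spec, truth[(group, phase)], seed, run_id=key, mask=mask
        )
        runs[key] = run
        confounds[key] = conf
        records.append(
            {
                "subject": subj,
                "group": group,
                "visit": visit,
                "phase": phase,
                "age": subjects[subj][1],
            }
        )
    design = pd.DataFrame.from_records(records)
    return Cohort(
        runs=runs, confounds=confounds, design=design, mask=mask, truth=truth, spec=spec
    )
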
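# falffpipe

A resting-state fMRI analysis pipeline for **fractional amplitude of
low-frequency fluctuations (fALFF)** group studies: confound regression and
band-pass denoising, the fALFF ratio statistic with rank-based inverse-normal
standardization, voxelwise GLM contrasts with cluster-level Gaussian
random-field inference and FDR correction, and paper-style cluster-table
reporting. A synthetic BOLD cohort generator with planted, analytically
predictable amplitude effects makes every stage testable without any MRI
download.

The package was built around a concurrent tDCS–rs-fMRI study design — two
groups (healthy controls and MS patients), two scanning phases per visit
(before and during stimulation), MS patients re-scanned after a course of
at-home stimulation sessions — but the stages are generic library functions.

## The statistic

For each voxel, after regressing nuisance signals (6 rigid-body motion
parameters, their first derivatives, per-scan outlier indicators, and WM/CSF
mean traces) from the BOLD series $y(t)$,

$$\mathrm{fALFF} \;=\; \frac{\mathrm{RMS}\big(y_{\mathrm{denoised}}
\text{ band-passed to } 0.01\text{–}0.1\ \mathrm{Hz}\big)}
{\mathrm{RMS}\big(y_{\mathrm{denoised}},\ \text{mean-removed}\big)} \in [0,1],$$

where the band-pass is an ideal DFT-domain projection, so fALFF² is exactly
the in-band fraction of the signal's nonzero-frequency power (Parseval).
Per run, in-mask fALFF values are standardized by the rank inverse-normal
transform $z_v = \Phi^{-1}\!\big((r_v - 0.5)/N\big)$, giving a zero-mean,
unit-variance map. Group contrasts (paired phase/visit differences; two-sample
group differences adjusted for age) yield voxelwise t-maps thresholded at
two-sided voxel p < 0.001; connected components (18-neighbour) receive
cluster-extent p-values from t-field random-field theory (with a
lattice-sampling correction validated against a permutation/Monte-Carlo
oracle; see `docs/methods.md`) and Benjamini–Hochberg FDR across clusters.

## Worked example

Simulate 20 paired subjects on a 24³ grid with a planted 150-voxel region
whose in-band amplitude is scaled ×1.5 during stimulation, then run the whole
pipeline in memory:

```python
import numpy as np
from falffpipe import SyntheticSpec, NoiseModel, EffectRoi, generate_cohort
from falffpipe.pipeline import analyze_cohort
from falffpipe.report import table_to_frame

shape = (24, 24, 24)
roi = EffectRoi.ball(center=(12, 12, 12), n_voxels=150, grid_shape=shape,
                     phase_scale=1.5)
spec = SyntheticSpec(grid_shape=shape, n_hc=20, n_ms=0, effect_rois=[roi],
                     seed=42, noise=NoiseModel(outlier_rate=0.0))
cohort = generate_cohort(spec)
result = analyze_cohort(cohort)

cres = result.contrasts["hc_baseline_phase"]
print("df =", cres.stat.df)
print("estimated FWHM (mm):", np.round(cres.smoothness.fwhm_mm, 2))
print(table_to_frame(cres.table_rows).round(4).to_string(index=False))
```

prints

```
df = 19
estimated FWHM (mm): [5.91 5.9  5.84]
Main Brain Regions Coordinates (x, y, z)  Voxels  Mean A (a.u.)  Mean B (a.u.)  Percentage Change (%)  T-Stat  P-FDR Direction
                       (-1.5, 1.5, -1.5)     279         0.0156         0.8912                96.5488 55.0123    0.0  increase
```

Reading: the paired during-minus-pre t-map (df = 19) contains one
FDR-surviving cluster of 279 voxels centred on the planted region (the extra
voxels are the 6 mm smoothing halo; Dice overlap with truth ≈ 0.72). The
mean normalized fALFF over the cluster rises from 0.016 (pre) to 0.891
(during), a percentage change of 96.5% by the absolute-value formula
((|dur| − |pre|)/(|dur| + |pre|)) × 100, and the estimated residual
smoothness (≈ 5.9 mm FWHM) recovers the applied 6 mm kernel.

The same analysis runs from the shell against on-disk NIfTI/TSV inputs:

```bash
falffpipe simulate --out data/ --seed 42 --grid 24,24,24 --n-hc 20 --n-ms 0 \
    --effect-voxels 150 --phase-scale 1.5
falffpipe all --config config.yaml      # paths + thresholds in the config
falffpipe report --output-dir out/
```

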
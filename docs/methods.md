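# Methods

This note documents the models and numerical choices behind falffpipe: what
each stage computes, which parameters matter, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely open.

## Pipeline overview

Stages run in this order: motion QC → confound regression → band-pass →
fALFF ratio → rank inverse-normal standardization → 6 mm spatial smoothing →
voxelwise GLM contrasts → cluster extraction → random-field cluster p-values →
FDR → cluster tables. All stages are deterministic given their inputs; the
only randomness in the package lives in the synthetic generator and the
permutation oracle, both driven by explicit seeds.

## Denoising

The nuisance model per run contains an intercept, the 6 rigid-body motion
traces (translations in mm, rotations in degrees), their first differences
(first sample 0), one indicator column per flagged outlier scan, and the WM
and CSF mean-signal traces — 15 columns plus one per outlier. A run with 23
or more outlier flags is rejected outright, mirroring the study's exclusion
rule. Exact-duplicate and all-zero columns are dropped with a warning; a
rank-deficient design after cleanup is an error naming the collinear columns.
Regression is per-voxel OLS via a QR projection of the design.

Outlier scans are flagged when framewise displacement exceeds 0.9 mm
(backward differences of the six traces; rotations converted to arc length on
a 50 mm sphere) or the global in-mask signal deviates more than 5 SD — the
published analysis names its outlier-detection tool family but not its
thresholds, so these conservative, commonly used defaults are configurable
(`fd_threshold_mm`, `global_z_threshold`).

The "WM/CSF linear trends (2 factors)" element is read as the two
mean-signal traces entered as regressors — the stated factor count fixes the
number of columns, not the estimator; a polynomial-detrend alternative can be
substituted by supplying different traces.

Band-pass filtering is an ideal (rectangular) DFT projection: real-FFT bins
with 0.01 ≤ f ≤ 0.1 Hz are retained, everything else including DC is zeroed.
Compared with a Butterworth filter this choice makes the fALFF ratio exactly
bounded in [0, 1] (orthogonal projection + Parseval) and analytically
testable; it assumes the series is treated as periodic, which is standard for
amplitude (not phase) statistics. Filtering is idempotent to machine
precision and splits energy exactly: ‖in-band‖² + ‖out-of-band‖² =
‖mean-removed input‖².

## fALFF and normalization

fALFF = RMS(band-passed denoised signal) / RMS(mean-removed denoised signal),
per voxel. The denominator is the confound-regressed, *unfiltered* residual:
"before band-pass filtering" is read as after confound regression, the only
reading under which the ratio is a pure band-fraction; a raw-signal
denominator is available via `falff_denominator="raw"`. Voxels with zero
residual variance are flagged undefined and excluded from the mask downstream;
an all-undefined run is an error.

The rank inverse-normal transform replaces each defined in-mask value by
Φ⁻¹((r − 0.5)/N) with average ranks for ties, independently per run. The
(r − 0.5)/N plotting position avoids ±∞ at the extremes; N counts defined
in-mask voxels only. The result has empirical mean 0 and variance ≈ 1 and is
invariant under any strictly monotone transform of the input map.

Smoothing order: fALFF is computed on unsmoothed residuals and the
*normalized* map is then smoothed at 6 mm FWHM (Gaussian, reflect boundary,
kernel truncated at 4σ) before group analysis. Smoothing the ratio map before
normalization instead is available via `smoothing_target="falff"`. Smoothing
last keeps the ratio's [0, 1] guarantee and the rank transform's exactness
per run; the cost is that the group-level maps are no longer rank-uniform
per subject, which is immaterial to the t-statistics.

## Group model

* Paired contrasts (during vs pre; follow-up vs baseline per phase) are
  one-sample t-tests on per-subject difference maps, df = n − 1. Subjects
  missing either condition are dropped from that contrast with a log entry.
* The between-group contrast is a two-sample GLM with mean-centered age as a
  nuisance covariate; the t for the group column is reported with
  df = n − p (covariate-adjusted) and, in metadata, the n − 2 convention that
  ignores the covariate, since published tables sometimes print the latter.
* Cluster-forming threshold: |t| > t⁻¹(1 − 0.0005; df), i.e. two-sided voxel
  p < 0.001; positive and negative excursions are labeled separately
  (18-neighbour connectivity by default; 6 and 26 available).

## Cluster-level inference

Smoothness is estimated from the standardized residual maps: the pooled
lag-1 spatial correlation ρ per axis is inverted under a Gaussian
autocorrelation model, σ² = −1/(4 ln ρ), FWHM = σ√(8 ln 2) voxels, floored at
1 voxel (a sampled field cannot be rougher than its grid; the floor is also
the estimate when ρ ≤ 0). RESELs = in-mask voxels / ∏ per-axis FWHM. On
simulated fields this estimator recovers an applied 2-voxel kernel to ~0.5%
and returns ~1 voxel for unsmoothed noise.

Cluster extent p-values follow the standard t-field construction — expected
suprathreshold volume E[N] = V·P(T > u), expected cluster count from the 3D
Euler-characteristic density ρ₃(u) per RESEL, expected continuum extent
E[S] = E[N]/E[m] — with one adaptation to sampled fields, calibrated against
Monte-Carlo simulation (the package's permutation oracle is the designated
correctness anchor):

* A cluster observed on the lattice occupies the continuum excursion's extent
  plus roughly one voxel of support: E[m]_lattice = E[N]/(E[S] + 1), and the
  extent survival is evaluated at k − 1.
* The excess extent S − 1 follows the *heavier* of two tails sharing the mean
  E[S]: the classical exp(−β k^{2/3}) law (accurate in the continuum regime,
  validated on 64³ fields at 2-voxel FWHM, agreement within a factor of 2 of
  the max-extent Monte-Carlo distribution throughout p ∈ [0.01, 0.2]) and a
  geometric law with ratio E[S]/(1 + E[S]) (accurate when E[S] is sub-voxel,
  validated on t₁₃ fields on a 24³ ellipsoid mask, where the continuum law
  alone is 2–3× anticonservative). Taking the maximum is a conservative
  envelope; both ingredients are first-principles approximations with the
  same first moment.

The per-cluster uncorrected p is this extent survival; a family-level
variant 1 − exp(−E[m]·P(S ≥ k)) (Poisson clumping) is available and is what
the Monte-Carlo comparison exercises. FDR across the clusters of one contrast
(both signs pooled by default; separable per sign) is Benjamini–Hochberg.

The permutation oracle uses subject-level sign flips for paired contrasts and
group-label shuffles for two-sample contrasts, with the max-cluster-extent
statistic and empirical p = (1 + #{null ≥ observed})/(1 + n_perm). It is a
validation instrument, not a user-facing alternative inference path.

## Reporting

Cluster tables mirror the published layout: per cluster, the group-mean
normalized fALFF per condition is computed per subject over the cluster's
voxels and then averaged across subjects (a pooled-voxel mean is the
documented alternative), and the percentage change is
((|b| − |a|)/(|b| + |a|)) × 100 on the condition means' absolute values —
bounded in [−100, 100], antisymmetric under swapping the inputs, invariant to
positive rescaling, undefined (flagged) only when both means are zero. The
same formula serves the between-group "relative difference"; which group is
larger follows the t-statistic's sign. Both the signed value and the
magnitude are stored, because published tables render either depending on
section. Peak coordinates are world mm via the NIfTI affine (RAS+); rows sort
by extent, descending, within direction; section totals are exact integer
sums. Optional atlas labels attach the majority label plus any label covering
≥ 10% of the cluster.

Note on the reference tables: recomputing each printed percentage from its
printed condition means reproduces it only to ~1e−3, consistent with the
means being rounded to 6 decimals upstream; the worked-example tests assert
at exactly that fidelity.

## Synthetic cohorts

The generator emulates the study's design and acquisition: 28 controls with
one visit and 20 patients with two visits, two phases per visit, 153
timepoints at TR = 2 s, 3 mm isotropic voxels on a 64×64×35 grid by default,
an ellipsoidal "brain" (semi-axes 0.45× the grid) of baseline intensity 1000.
Each in-mask voxel's series is

    1000 + drift + scale × band-limited component + AR(1) broadband noise.

* The band-limited component is synthesized on the DFT bins inside
  0.01–0.1 Hz with fixed per-bin amplitudes and random phases, so its
  realized in-band power is exactly (scale × in_band_sigma)²: planted
  amplitude scales translate into in-band power ratios of scale² with no
  sampling slack.
* Broadband noise is stationary AR(1) (coefficient 0.3, marginal SD 1 by
  default); drift is a per-voxel linear ramp with N(0, 1) total excursion;
  defaults put roughly as much broadband as band-limited power in a voxel,
  a regime in which the fALFF statistic is informative but not saturated.
* Effect regions multiply the in-band amplitude in the "during" phase
  (phase_scale) and/or in the patient group (group_scale); truth maps per
  group × phase are returned for recovery scoring. No magnitude anchor for
  real stimulation effects exists in the source material; the default test
  effect (150 voxels, scale 1.5) was chosen for testability.
* Motion traces are smoothed random walks (zero at the first scan, RMS set by
  motion_sigma — 0.1 mm / 0.1° by default, comfortably inside the QC limits);
  they are emitted as confounds but never applied to the volumes, so the QC
  and regression paths are exercised without implementing realignment.
  Flagged outlier scans (rate 0.02/scan) receive a global intensity spike so
  data-driven detection has a signal. WM/CSF traces are unit-variance AR(1)
  series.

What the generator does **not** emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) quasi-periodicity, spatial noise
correlation within a run (spatial structure enters only through smoothing),
susceptibility artifacts, actual head-motion resampling, or
lesion/atrophy anatomy. Passing tests therefore demonstrate statistical
correctness of the pipeline under a known generative model — error control,
calibration, recovery — not robustness to every artifact of real MRI data.

Determinism: a cohort is generated from a root seed via spawned per-run
seed sequences; identical specs give bit-identical cohorts, and every
acceptance simulation is seeded.

## Problem sizes used in validation

Validation simulations run at deliberately reduced sizes chosen to estimate
each quantity with useful precision: null error control uses 200 cohorts of
14 paired subjects on 24³ grids; random-field calibration uses 500 smooth
64³ fields; recovery uses 20 cohorts of 20 paired subjects. The generator's
defaults remain the full acquisition geometry.

## Known limitations

* The random-field extent model is an approximation; at cluster-forming
  thresholds far from p = 0.001 or smoothness below ~1.5 voxels FWHM its
  calibration should be re-checked against the permutation oracle.
* The repeated-measures structure of the two-visit patient group is handled
  by paired contrasts per phase, not a full multivariate random-effects
  model; an unpaired visit contrast is available via configuration.
* FDR is applied across the clusters of one contrast; no across-contrast
  correction is attempted.
* The ideal band-pass assumes the analysis band lies strictly below Nyquist;
  series shorter than 16 samples are rejected rather than filtered.
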
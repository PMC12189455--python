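"""Regressor construction, outlier detection, confound regression and the
ideal band-pass filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from falffpipe import (
    RunRejectedError,
    bandpass,
    build_regressor_matrix,
    detect_outlier_scans,
    regress_confounds,
)
from falffpipe.denoise import band_bin_indices, denoise_run
from tests.conftest import full_mask, make_confounds, make_run


def rand_confounds(rng, t, n_out=0):
    flags = np.zeros(t, dtype=bool)
    flags[:n_out] = True
    return make_confounds(
        t,
        motion=rng.normal(0, 0.1, (t, 6)),
        flags=flags,
        wm=rng.normal(size=t),
        csf=rng.normal(size=t),
    )


class TestRegressorMatrix:
    def test_column_count_without_outliers(self, rng):
        X = build_regressor_matrix(rand_confounds(rng, 64))
        assert X.n_columns == 1 + 12 + 2 == 15
        assert X.labels[0] == "intercept"

    def test_outlier_indicator_columns(self, rng):
        X = build_regressor_matrix(rand_confounds(rng, 64, n_out=5))
        assert X.n_columns == 20
        out_cols = [j for j, lab in enumerate(X.labels) if lab.startswith("outlier_")]
        assert len(out_cols) == 5
        for j in out_cols:
            assert X.values[:, j].sum() == 1.0

    def test_outlier_limit_rejects_run(self, rng):
        with pytest.raises(RunRejectedError, match="outlier limit"):
            build_regressor_matrix(rand_confounds(rng, 64, n_out=23))
        # 22 flags is still accepted
        build_regressor_matrix(rand_confounds(rng, 64, n_out=22))

    def test_duplicate_and_zero_columns_dropped(self):
        t = 32
        conf = make_confounds(t, motion=np.zeros((t, 6)))  # all motion zero
        X = build_regressor_matrix(conf)
        assert X.labels == ["intercept"]

    def test_derivative_first_sample_zero(self, rng):
        conf = rand_confounds(rng, 16)
        assert np.all(conf.motion_derivatives[0] == 0)
        np.testing.assert_allclose(
            conf.motion_derivatives[1:], np.diff(conf.motion, axis=0)
        )


class TestOutlierDetection:
    def test_quiet_run_has_no_flags(self, rng):
        t = 64
        run = make_run(1000 + rng.normal(0, 1, (4, 4, 4, t)))
        conf = make_confounds(t)
        assert not detect_outlier_scans(run, conf).any()

    def test_translation_jump_flagged_via_fd(self, rng):
        t = 64
        run = make_run(1000 + rng.normal(0, 1, (4, 4, 4, t)))
        motion = np.zeros((t, 6))
        motion[30:, 0] = 2.0  # 2 mm jump at scan 30
        flags = detect_outlier_scans(run, make_confounds(t, motion=motion))
        assert flags[30] and flags.sum() == 1

    def test_global_spike_flagged_via_zscore(self, rng):
        t = 64
        data = 1000 + rng.normal(0, 1, (4, 4, 4, t))
        data[..., 40] += 8 * data.std()
        flags = detect_outlier_scans(make_run(data), make_confounds(t))
        assert flags[40]

    def test_existing_flags_are_kept(self, rng):
        t = 64
        run = make_run(1000 + rng.normal(0, 1, (4, 4, 4, t)))
        pre = np.zeros(t, dtype=bool)
        pre[5] = True
        flags = detect_outlier_scans(run, make_confounds(t, flags=pre))
        assert flags[5]


class TestRegression:
    def test_perfect_fit_gives_zero_residual(self, rng):
        t = 64
        conf = rand_confounds(rng, t)
        X = build_regressor_matrix(conf)
        series = conf.motion[:, 0]
        run = make_run(np.broadcast_to(series, (3, 3, 3, t)).copy())
        resid = regress_confounds(run, X)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_orthogonal_series_untouched(self, rng):
        t = 64
        conf = make_confounds(t)  # intercept-only model after cleanup
        X = build_regressor_matrix(conf)
        series = np.sin(2 * np.pi * np.arange(t) / 8)  # mean-zero
        run = make_run(np.broadcast_to(series, (2, 2, 2, t)).copy())
        resid = regress_confounds(run, X)
        np.testing.assert_allclose(resid[0, 0, 0], series, atol=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        t = 96
        conf = rand_confounds(rng, t, n_out=3)
        X = build_regressor_matrix(conf)
        run = make_run(rng.normal(size=(4, 4, 2, t)))
        resid = regress_confounds(run, X).reshape(-1, t)
        for j in range(X.n_columns):
            col = X.values[:, j]
            cos = np.abs(resid @ col) / (
                np.linalg.norm(col) * np.linalg.norm(resid, axis=1)
            )
            assert cos.max() < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        t = 48
        conf = rand_confounds(rng, t, n_out=2)
        X = build_regressor_matrix(conf)
        data = rng.normal(size=(20, t))  # 20-voxel toy run
        run = make_run(data.reshape(4, 5, 1, t))
        resid = regress_confounds(run, X).reshape(-1, t)
        A = X.values
        beta = np.linalg.solve(A.T @ A, A.T @ data.T)
        expected = data - (A @ beta).T
        assert np.max(np.abs(resid - expected)) < 1e-10

    def test_rank_deficient_design_names_columns(self, rng):
        t = 32
        conf = rand_confounds(rng, t)
        X = build_regressor_matrix(conf)
        X.values[:, 2] = 2 * X.values[:, 1]  # force collinearity post-cleanup
        run = make_run(rng.normal(size=(2, 2, 2, t)))
        with pytest.raises(ValueError, match="collinear"):
            regress_confounds(run, X)


class TestBandpass:
    def test_retained_bin_sinusoid_is_eigenfunction(self):
        t, tr = 160, 2.0
        x = np.cos(2 * np.pi * 0.05 * tr * np.arange(t))  # bin 16, in band
        np.testing.assert_allclose(bandpass(x, tr), x, atol=1e-10)

    def test_excluded_bin_sinusoid_annihilated(self):
        t, tr = 160, 2.0
        x = np.cos(2 * np.pi * 0.2 * tr * np.arange(t))  # bin 64, out of band
        np.testing.assert_allclose(bandpass(x, tr), 0.0, atol=1e-10)

    def test_dc_removed(self):
        x = np.full(64, 5.0)
        np.testing.assert_allclose(bandpass(x, 2.0), 0.0, atol=1e-12)

    def test_idempotent_projection(self, rng):
        x = rng.normal(size=(7, 153))
        once = bandpass(x, 2.0)
        twice = bandpass(once, 2.0)
        assert np.max(np.abs(once - twice)) < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([64, 153, 160]))
    def test_parseval_energy_split(self, seed, t):
        """In-band energy + out-of-band energy = total mean-removed energy."""
        x = np.random.default_rng(seed).normal(size=t)
        xc = x - x.mean()
        inband = bandpass(x, 2.0)
        rest = xc - inband
        total = np.sum(xc**2)
        assert np.sum(inband**2) + np.sum(rest**2) == pytest.approx(total, rel=1e-8)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(64), tr_s=2.0, f_lo=0.01, f_hi=0.3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(8), 2.0)

    def test_band_bins_for_study_acquisition(self):
        """153 timepoints at TR 2 s: band 0.01-0.1 Hz covers rfft bins 4..30."""
        bins = band_bin_indices(153, 2.0, 0.01, 0.1)
        assert bins[0] == 4 and bins[-1] == 30 and len(bins) == 27


class TestDenoiseRun:
    def test_residual_pair_consistency(self, rng):
        """Filtering the stored unfiltered residual reproduces the stored
        filtered residual (order invariance within the contract)."""
        t = 96
        run = make_run(1000 + rng.normal(0, 5, (5, 5, 5, t)))
        conf = rand_confounds(rng, t)
        mask = full_mask((5, 5, 5))
        den = denoise_run(run, conf, mask=mask, detect_outliers=False)
        np.testing.assert_allclose(
            bandpass(den.residual_unfiltered, run.tr_s),
            den.residual_filtered,
            atol=1e-10,
        )
        # per-voxel means ~ 0
        assert np.max(np.abs(den.residual_unfiltered.mean(axis=-1))) < 1e-10
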
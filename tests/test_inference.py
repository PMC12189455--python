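"""Voxelwise contrasts, smoothness estimation, cluster extraction, GRF
extent p-values, FDR and the permutation oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from falffpipe import (
    Contrast,
    StatMap,
    cluster_forming_threshold,
    estimate_smoothness,
    extract_clusters,
    fdr_correct,
    fit_voxelwise_contrast,
    grf_cluster_pvalue,
    permutation_cluster_test,
)
from falffpipe.inference import SmoothnessEstimate, one_sample_t
from falffpipe.preprocess import smooth_gaussian
from tests.conftest import full_mask

PAIRED = Contrast(kind="paired", condition_col="phase", condition_a="during", condition_b="pre")


def paired_design(n):
    rows = []
    for i in range(n):
        for phase in ("pre", "during"):
            rows.append({"subject": f"S{i:02d}", "group": "HC", "visit": "baseline",
                         "phase": phase, "age": 40.0})
    return pd.DataFrame(rows)


class TestVoxelwiseContrast:
    def test_identical_phases_give_zero_t(self, rng):
        n = 6
        design = paired_design(n)
        base = rng.normal(size=(n, 4, 4, 4))
        maps = np.repeat(base, 2, axis=0)  # pre == during per subject
        stat = fit_voxelwise_contrast(maps, design, PAIRED, full_mask((4, 4, 4)))
        np.testing.assert_allclose(stat.t_values, 0.0, atol=1e-12)

    def test_paired_df_is_n_minus_one(self, rng):
        n = 20
        maps = rng.normal(size=(2 * n, 3, 3, 3))
        stat = fit_voxelwise_contrast(maps, paired_design(n), PAIRED, full_mask((3, 3, 3)))
        assert stat.df == 19

    def test_matches_hand_computed_one_sample_t(self, rng):
        n = 6
        design = paired_design(n)
        maps = rng.normal(size=(2 * n, 3, 3, 3))
        stat = fit_voxelwise_contrast(maps, design, PAIRED, full_mask((3, 3, 3)))
        # oracle: explicit per-subject differences and textbook t formula
        diffs = np.array([maps[2 * i + 1] - maps[2 * i] for i in range(n)])
        mean = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=1)
        expected = mean / (sd / np.sqrt(n))
        assert np.max(np.abs(stat.t_values - expected)) < 1e-10

    def test_unmatched_pairs_error_names_subject(self, rng):
        design = paired_design(4).drop(3).reset_index(drop=True)  # S01 loses 'during'
        maps = rng.normal(size=(7, 2, 2, 2))
        with pytest.raises(ValueError, match="S01"):
            fit_voxelwise_contrast(maps, design, PAIRED, full_mask((2, 2, 2)))

    def test_two_sample_with_age_covariate_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n_a, n_b = 10, 8
        design = pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(n_a + n_b)],
                "group": ["HC"] * n_a + ["MS"] * n_b,
                "visit": "baseline",
                "phase": "pre",
                "age": rng.uniform(20, 70, n_a + n_b),
            }
        )
        maps = rng.normal(size=(n_a + n_b, 2, 2, 1))
        contrast = Contrast(kind="two_sample", group_a="HC", group_b="MS", covariates=("age",))
        stat = fit_voxelwise_contrast(maps, design, contrast, full_mask((2, 2, 1)))
        assert stat.df == n_a + n_b - 3
        assert stat.df_unadjusted == n_a + n_b - 2
        y = maps[:, 0, 0, 0]
        X = sm.add_constant(
            np.column_stack(
                [(design.group == "HC").astype(float), design.age - design.age.mean()]
            )
        )
        fit = sm.OLS(y, X).fit()
        assert stat.t_values[0, 0, 0] == pytest.approx(fit.tvalues[1], abs=1e-10)


class TestSmoothness:
    def test_white_noise_fwhm_near_one_voxel(self, rng):
        """Unsmoothed Gaussian noise: estimated FWHM ~ 1 voxel (within 15%)."""
        mask = full_mask((16, 16, 16))
        est = []
        for _ in range(50):
            maps = rng.normal(size=(8, 16, 16, 16))
            est.append(estimate_smoothness(maps, mask, 3.0).fwhm_vox.mean())
        assert np.mean(est) == pytest.approx(1.0, rel=0.15)

    def test_smoothed_noise_fwhm_recovers_kernel(self, rng):
        """Noise smoothed at 6 mm on 3 mm voxels: estimate in (1.7, 2.4) vox."""
        mask = full_mask((16, 16, 16))
        est = []
        for _ in range(50):
            maps = np.stack(
                [smooth_gaussian(rng.normal(size=(16, 16, 16)), 6.0, 3.0) for _ in range(8)]
            )
            est.append(estimate_smoothness(maps, mask, 3.0).fwhm_vox.mean())
        assert 1.7 < np.mean(est) < 2.4

    def test_resels_proportional_to_mask_volume(self, rng):
        maps = rng.normal(size=(6, 20, 10, 10))
        half = np.zeros((20, 10, 10), bool)
        half[:10] = True
        m_full = full_mask((20, 10, 10))
        m_half = full_mask((20, 10, 10))
        m_half.data = half
        r_full = estimate_smoothness(maps, m_full, 3.0)
        r_half = estimate_smoothness(maps, m_half, 3.0)
        # white noise: FWHM pinned at the 1-voxel floor, so resels track volume
        assert r_full.resels == pytest.approx(2 * r_half.resels, rel=0.05)

    def test_requires_two_maps(self, rng):
        with pytest.raises(ValueError, match="2 residual maps"):
            estimate_smoothness(rng.normal(size=(1, 4, 4, 4)), full_mask((4, 4, 4)))


class TestClusterExtraction:
    def stat_from(self, t3, df=19):
        return StatMap(t_values=np.asarray(t3, dtype=float), df=df)

    def test_single_suprathreshold_voxel(self):
        t3 = np.zeros((5, 5, 5))
        t3[2, 2, 2] = 10.0
        clusters = extract_clusters(self.stat_from(t3), full_mask((5, 5, 5)))
        assert len(clusters) == 1
        assert clusters[0].size_voxels == 1
        assert clusters[0].sign == "increase"

    def test_edge_neighbours_join_under_18_connectivity(self):
        t3 = np.zeros((5, 5, 5))
        t3[2, 2, 2] = t3[2, 3, 3] = 10.0  # share an edge
        clusters = extract_clusters(self.stat_from(t3), full_mask((5, 5, 5)), connectivity=18)
        assert len(clusters) == 1 and clusters[0].size_voxels == 2
        # corner neighbours only join under 26-connectivity
        t3c = np.zeros((5, 5, 5))
        t3c[2, 2, 2] = t3c[3, 3, 3] = 10.0
        assert len(extract_clusters(self.stat_from(t3c), full_mask((5, 5, 5)), connectivity=18)) == 2
        assert len(extract_clusters(self.stat_from(t3c), full_mask((5, 5, 5)), connectivity=26)) == 1

    def test_signs_separated(self):
        t3 = np.zeros((5, 5, 5))
        t3[1, 1, 1], t3[1, 1, 2] = 10.0, -10.0
        clusters = extract_clusters(self.stat_from(t3), full_mask((5, 5, 5)))
        assert {c.sign for c in clusters} == {"increase", "decrease"}

    def test_matches_flood_fill_oracle(self, rng):
        """Random 10^3 excursion sets: partition equals exhaustive flood fill."""
        excursion = rng.random((10, 10, 10)) < 0.25
        t3 = np.where(excursion, 10.0, 0.0)
        clusters = extract_clusters(self.stat_from(t3), full_mask((10, 10, 10)))
        # brute-force flood fill with 18-neighbour adjacency
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= 2
        ]
        seen = np.zeros_like(excursion)
        components = []
        for start in zip(*np.nonzero(excursion)):
            if seen[start]:
                continue
            stack, comp = [start], set()
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.add(v)
                for d in offsets:
                    w = tuple(np.add(v, d))
                    if all(0 <= w[i] < 10 for i in range(3)) and excursion[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
            components.append(frozenset(comp))
        ours = {frozenset(zip(*c.voxel_indices)) for c in clusters}
        assert ours == set(components)

    def test_peak_is_max_abs_t_smallest_index_on_ties(self):
        t3 = np.zeros((5, 5, 5))
        t3[1, 1, 1] = t3[1, 1, 2] = 10.0
        c = extract_clusters(self.stat_from(t3), full_mask((5, 5, 5)))[0]
        assert c.peak_index == (1, 1, 1)

    def test_threshold_is_two_sided_quantile(self):
        u = cluster_forming_threshold(19, 0.001)
        assert u == pytest.approx(stats.t.isf(0.0005, 19), abs=1e-12)


def flat_smoothness(n_mask, fwhm_vox=2.0):
    f = np.full(3, float(fwhm_vox))
    return SmoothnessEstimate(
        fwhm_vox=f, fwhm_mm=f * 3, resels=n_mask / fwhm_vox**3, n_mask_voxels=n_mask
    )


class TestGrfPvalue:
    def test_limits(self):
        sm_ = flat_smoothness(10000)
        u = cluster_forming_threshold(19, 0.001)
        assert grf_cluster_pvalue(0, sm_, u, 19) == 1.0
        assert grf_cluster_pvalue(1, sm_, u, 19) == 1.0  # lattice floor
        assert grf_cluster_pvalue(100000, sm_, u, 19) < 1e-10

    def test_monotone_decreasing_in_extent(self):
        sm_ = flat_smoothness(10000)
        u = cluster_forming_threshold(19, 0.001)
        p = [grf_cluster_pvalue(k, sm_, u, 19) for k in (50, 100, 200)]
        assert p[0] > p[1] > p[2]

    def test_monotone_increasing_in_smoothness(self):
        u = cluster_forming_threshold(19, 0.001)
        p_rough = grf_cluster_pvalue(100, flat_smoothness(10000, 1.5), u, 19)
        p_smooth = grf_cluster_pvalue(100, flat_smoothness(10000, 3.0), u, 19)
        assert p_smooth > p_rough

    def test_larger_cluster_never_less_significant_within_field(self):
        sm_ = flat_smoothness(5000)
        u = cluster_forming_threshold(13, 0.001)
        sizes = [1, 5, 20, 80]
        ps = [grf_cluster_pvalue(k, sm_, u, 13) for k in sizes]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_smoothness_rejected(self):
        bad = SmoothnessEstimate(
            fwhm_vox=np.zeros(3), fwhm_mm=np.zeros(3), resels=0.0, n_mask_voxels=100
        )
        with pytest.raises(ValueError, match="smoothness"):
            grf_cluster_pvalue(10, bad, 3.3, 19)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.01] * 5), 0.01)

    def test_matches_hand_step_up(self):
        q = fdr_correct([0.01, 0.02, 0.03, 0.20])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.20], atol=1e-12)

    def test_empty_list(self):
        assert len(fdr_correct([])) == 0

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 20)
        q = fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPermutationOracle:
    def null_maps(self, rng, n, shape=(8, 8, 8)):
        maps = rng.normal(size=(2 * n, *shape))
        return maps, paired_design(n)

    def test_seed_determinism(self, rng):
        maps, design = self.null_maps(rng, 8)
        mask = full_mask((8, 8, 8))
        a, null_a = permutation_cluster_test(maps, design, PAIRED, mask, n_perm=120, seed=5)
        b, null_b = permutation_cluster_test(maps, design, PAIRED, mask, n_perm=120, seed=5)
        np.testing.assert_array_equal(null_a, null_b)
        assert [c.p_grf_uncorrected for c in a] == [c.p_grf_uncorrected for c in b]

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        n = 12
        design = paired_design(n)
        mask = full_mask((8, 8, 8))
        # plant an effect strong enough that only the unflipped sign pattern
        # reaches the observed extent, so p hits the resolution floor
        maps = rng.normal(size=(2 * n, 8, 8, 8))
        maps[1::2, 2:5, 2:5, 2:5] += 3.0
        clusters, _ = permutation_cluster_test(maps, design, PAIRED, mask, n_perm=199, seed=1)
        top = max(clusters, key=lambda c: c.size_voxels)
        assert top.p_grf_uncorrected == pytest.approx(1 / 200)

    def test_null_p_distribution_is_valid(self, rng):
        """Under the null the empirical max-extent p is stochastically no
        smaller than uniform: rejection rates stay at or below nominal."""
        n = 10
        design = paired_design(n)
        mask = full_mask((10, 10, 10))
        pvals = []
        for _ in range(120):
            maps = rng.normal(size=(2 * n, 10, 10, 10))
            clusters, null = permutation_cluster_test(
                maps, design, PAIRED, mask, n_perm=99, seed=int(rng.integers(2**31)),
                voxel_p=0.01,
            )
            obs = max((c.size_voxels for c in clusters), default=0)
            pvals.append((1 + (null >= obs).sum()) / (1 + 99))
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.1, 0.2):
            rate = (pvals <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert rate <= alpha + 3 * se
        # and the test has power to reject at all: small p-values do occur
        assert (pvals <= 0.35).mean() >= 0.05
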
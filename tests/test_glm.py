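import dataclasses

import numpy as np
import pytest

import petref
from petref import (
    SubjectMeta,
    build_design_matrix,
    contrast_tmap,
    default_ageing_model,
    fit_voxelwise_ols,
    fold_ratios,
    label_clusters,
    permutation_fwe_threshold,
    run_glm,
    significant_volume_report,
    simulate_cohort,
)
from petref.glm import DesignMatrix


def small_cohort(n=8, seed=0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(25, 85, size=n)
    sexes = rng.integers(0, 2, size=n)
    sexes[:2] = [0, 1]  # both sexes present
    return [SubjectMeta(f"s{i}", float(ages[i]), int(sexes[i])) for i in range(n)]


class TestDesignMatrix:
    def test_intercept_column(self):
        d = build_design_matrix(small_cohort(5))
        assert d.X.shape == (5, 3)
        assert np.all(d.X[:, 0] == 1)

    def test_single_sex_cohort_rejected(self):
        cohort = [SubjectMeta(f"s{i}", 30.0 + i, 0) for i in range(6)]
        with pytest.raises(ValueError, match="rank"):
            build_design_matrix(cohort)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="5 subjects"):
            build_design_matrix(small_cohort(4))

    def test_age_centering_leaves_t_unchanged(self):
        cohort = small_cohort(10, seed=1)
        rng = np.random.default_rng(2)
        vols = rng.random((10, 4, 4, 4)) + 1.0
        mask = np.ones((4, 4, 4), dtype=bool)
        d = build_design_matrix(cohort)
        t1 = contrast_tmap(fit_voxelwise_ols(vols, d, mask), d)
        Xc = d.X.copy()
        Xc[:, 1] -= Xc[:, 1].mean()
        dc = DesignMatrix(X=Xc)
        t2 = contrast_tmap(fit_voxelwise_ols(vols, dc, mask), dc)
        assert np.allclose(t1, t2, atol=1e-10)


class TestVoxelwiseOLS:
    def test_exact_linear_data_recovered(self):
        cohort = small_cohort(10, seed=3)
        ages = np.array([m.age for m in cohort])
        vols = np.empty((10, 3, 3, 3))
        vols[:] = (2.0 - 0.03 * ages)[:, None, None, None]
        mask = np.ones((3, 3, 3), dtype=bool)
        d = build_design_matrix(cohort)
        fit = fit_voxelwise_ols(vols, d, mask)
        assert np.allclose(fit.beta[0], 2.0, atol=1e-10)
        assert np.allclose(fit.beta[1], -0.03, atol=1e-12)
        assert np.allclose(fit.beta[2], 0.0, atol=1e-10)
        assert np.all(fit.sigma2 == 0.0)
        # perfect decline -> +inf marker under the negative-age contrast
        t = contrast_tmap(fit, d)
        assert np.all(np.isposinf(t[mask]))

    def test_single_voxel_matches_normal_equations_oracle(self):
        cohort = small_cohort(8, seed=4)
        rng = np.random.default_rng(5)
        y = rng.random(8) * 10
        vols = y[:, None, None, None] * np.ones((8, 1, 1, 1))
        mask = np.ones((1, 1, 1), dtype=bool)
        d = build_design_matrix(cohort)
        fit = fit_voxelwise_ols(vols, d, mask)
        X = d.X
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta_oracle) ** 2).sum())
        assert np.allclose(fit.beta[:, 0], beta_oracle, atol=1e-10)
        assert fit.sigma2[0] == pytest.approx(rss / 5, abs=1e-10)
        t = contrast_tmap(fit, d)
        c = np.array([0.0, -1.0, 0.0])
        t_oracle = (c @ beta_oracle) / np.sqrt(
            rss / 5 * c @ np.linalg.inv(X.T @ X) @ c
        )
        assert t[0, 0, 0] == pytest.approx(t_oracle, abs=1e-10)

    def test_subject_permutation_invariance(self):
        cohort = small_cohort(9, seed=6)
        rng = np.random.default_rng(7)
        vols = rng.random((9, 3, 3, 3)) + 1
        mask = np.ones((3, 3, 3), dtype=bool)
        d = build_design_matrix(cohort)
        t1 = contrast_tmap(fit_voxelwise_ols(vols, d, mask), d)
        perm = rng.permutation(9)
        dp = DesignMatrix(X=d.X[perm])
        t2 = contrast_tmap(fit_voxelwise_ols(vols[perm], dp, mask), dp)
        assert np.allclose(t1, t2, atol=1e-10)

    def test_flipping_contrast_negates_map(self):
        cohort = small_cohort(9, seed=8)
        rng = np.random.default_rng(9)
        vols = rng.random((9, 3, 3, 3)) + 1
        mask = np.ones((3, 3, 3), dtype=bool)
        d = build_design_matrix(cohort)
        fit = fit_voxelwise_ols(vols, d, mask)
        t_neg = contrast_tmap(fit, d, contrast=(0, -1, 0))
        t_pos = contrast_tmap(fit, d, contrast=(0, 1, 0))
        assert np.allclose(t_neg, -t_pos, atol=0)

    def test_zero_over_zero_is_zero(self):
        cohort = small_cohort(8, seed=10)
        vols = np.full((8, 2, 2, 2), 5.0)  # constant in subjects: beta_age = 0, rss = 0
        mask = np.ones((2, 2, 2), dtype=bool)
        d = build_design_matrix(cohort)
        t = contrast_tmap(fit_voxelwise_ols(vols, d, mask), d)
        assert np.all(t == 0.0)

    def test_non_finite_voxel_named(self):
        cohort = small_cohort(8, seed=11)
        vols = np.ones((8, 2, 2, 2))
        vols[3, 1, 0, 1] = np.nan
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="subject index 3"):
            fit_voxelwise_ols(vols, build_design_matrix(cohort), mask)


@pytest.fixture(scope="module")
def null_data():
    rng = np.random.default_rng(12)
    cohort = small_cohort(12, seed=12)
    vols = rng.random((12, 5, 5, 5)) + 1
    mask = np.ones((5, 5, 5), dtype=bool)
    return vols, build_design_matrix(cohort), mask


class TestPermutationThreshold:
    def test_alpha_one_gives_null_minimum(self, null_data):
        vols, d, mask = null_data
        thr_all = permutation_fwe_threshold(vols, d, mask, n_perm=100, alpha=1.0, seed=0)
        thr_05 = permutation_fwe_threshold(vols, d, mask, n_perm=100, alpha=0.05, seed=0)
        assert thr_all < thr_05

    def test_deterministic_given_seed(self, null_data):
        vols, d, mask = null_data
        a = permutation_fwe_threshold(vols, d, mask, n_perm=150, alpha=0.05, seed=42)
        b = permutation_fwe_threshold(vols, d, mask, n_perm=150, alpha=0.05, seed=42)
        assert a == b

    def test_insufficient_permutations_rejected(self, null_data):
        vols, d, mask = null_data
        with pytest.raises(ValueError, match="insufficient permutations"):
            permutation_fwe_threshold(vols, d, mask, n_perm=99)


class TestLabelClusters:
    def test_counting_and_volume_ordering(self):
        tmap = np.zeros((10, 10, 10))
        tmap[1, 1, 1:6] = 5.0  # 5 voxels
        tmap[7, 7, 1:8] = 4.5  # 7 voxels
        clusters = label_clusters(tmap, 4.0, (2, 2, 2))
        assert [c.volume_mm3 for c in clusters] == [56.0, 40.0]
        assert [c.n_voxels for c in clusters] == [7, 5]
        assert clusters[1].t_max == 5.0
        assert clusters[1].peak_ijk == (1, 1, 1)

    def test_corner_touching_blobs_merge_under_26_connectivity(self):
        tmap = np.zeros((6, 6, 6))
        tmap[1, 1, 1] = 5.0
        tmap[2, 2, 2] = 5.0  # shares only a corner
        assert len(label_clusters(tmap, 4.0, (1, 1, 1), connectivity=26)) == 1
        assert len(label_clusters(tmap, 4.0, (1, 1, 1), connectivity=6)) == 2

    def test_threshold_above_global_max_gives_empty_list(self):
        tmap = np.random.default_rng(0).random((5, 5, 5))
        assert label_clusters(tmap, 2.0, (2, 2, 2)) == []

    def test_infinite_peaks_cluster(self):
        tmap = np.zeros((5, 5, 5))
        tmap[2, 2, 2] = np.inf
        clusters = label_clusters(tmap, 4.0, (2, 2, 2))
        assert len(clusters) == 1 and np.isinf(clusters[0].t_max)


class TestVolumeReport:
    def test_published_conventional_fold_ratio(self):
        folds = fold_ratios({"pons": 143330.0, "cerebellum": 84216.0, "whole_gm": 41528.0})
        assert round(folds["cerebellum"], 1) == 1.7
        assert min(round(v, 1) for k, v in folds.items() if k != "pons") == 1.7

    def test_published_digital_fold_ratio(self):
        folds = fold_ratios({"pons": 453080.0, "cerebellum": 183378.0, "whole_gm": 63079.0})
        assert round(folds["cerebellum"], 1) == 2.5

    def test_identical_volumes_give_unit_ratio(self):
        folds = fold_ratios({"a": 1000.0, "b": 1000.0})
        assert folds == {"a": 1.0, "b": 1.0}

    def test_report_orders_by_volume(self, toy_atlas):
        cfg = petref.preset("digital", seed=2, n_subjects=20, n_women=10)
        model = default_ageing_model(toy_atlas.region_names, seed=2, reference_age=cfg.age_mean)
        cohort, _, vols = simulate_cohort(toy_atlas, model, cfg)
        d = build_design_matrix(cohort)
        mask = toy_atlas.brain_mask()
        results = {
            ref: run_glm(
                petref.scale_volumes_by_reference(vols, toy_atlas, ref),
                d, mask, toy_atlas.voxel_size_mm, n_perm=100, seed=2,
            )
            for ref in ("Pons", petref.WHOLE_GREY_MATTER)
        }
        report = significant_volume_report(results)
        assert list(report.columns[:2]) == ["reference", "total_significant_mm3"]
        assert report["total_significant_mm3"].is_monotonic_decreasing


def test_image_and_matrix_level_normalization_commute(tiny_atlas, noise_free_config):
    """On piecewise-constant images, dividing volumes by the reference ROI
    mean equals extracting first and dividing the matrix."""
    cfg = dataclasses.replace(noise_free_config, global_factor_sd=0.3)
    model = default_ageing_model(tiny_atlas.region_names, seed=5, reference_age=cfg.age_mean)
    cohort, means, vols = simulate_cohort(tiny_atlas, model, cfg)
    matrix = petref.matrix_from_region_means(cohort, means, tiny_atlas.region_names)
    suvr_matrix = petref.normalize_by_reference(matrix, "Pons")
    scaled_vols = petref.scale_volumes_by_reference(vols, tiny_atlas, "Pons")
    extracted = np.vstack([
        petref.extract_region_means(v, tiny_atlas, include_whole_grey_matter=False)
        for v in scaled_vols
    ])
    assert np.allclose(extracted, suvr_matrix.values, atol=1e-10)
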
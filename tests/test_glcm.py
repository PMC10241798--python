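import numpy as np
import pytest

import petromics as pm
from petromics.errors import DataError
from petromics.glcm import (
    GLCMMatrix,
    OFFSETS_2D_AXIAL,
    OFFSETS_3D,
    build_glcm,
    discretize,
    glcm_features,
    texture_pipeline,
)
from petromics.segmentation import VOIMask

from _oracles import glcm_counts_oracle, glcm_features_oracle


def _volume_mask(arr, spacing=(2.0, 2.0, 2.0)):
    arr = np.asarray(arr, float)
    vol = pm.SUVVolume(arr, spacing)
    mask = VOIMask(np.ones(arr.shape, bool), spacing)
    return vol, mask


class TestDiscretize:
    def test_two_bin_split(self):
        vol, mask = _volume_mask(np.arange(11.0).reshape(11, 1, 1))
        lv = discretize(vol, mask, n_levels=2, value_range=(0, 10))
        got = lv.levels[:, 0, 0]
        assert list(got) == [1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2]

    def test_constant_image_all_level_one_flagged(self):
        vol, mask = _volume_mask(np.full((3, 3, 3), 4.0))
        lv = discretize(vol, mask, n_levels=8)
        assert lv.constant
        assert np.all(lv.levels[mask.mask] == 1)

    def test_linear_ramp_fills_levels_equally(self):
        n_levels = 16
        vol, mask = _volume_mask(np.linspace(0, 1, 64).reshape(64, 1, 1))
        lv = discretize(vol, mask, n_levels=n_levels)
        counts = np.bincount(lv.levels[mask.mask], minlength=n_levels + 1)[1:]
        assert counts.sum() == 64
        assert counts.max() - counts.min() <= 1

    def test_out_of_mask_is_zero(self):
        arr = np.full((4, 4, 4), 5.0)
        vol = pm.SUVVolume(arr, (2, 2, 2))
        m = np.zeros(arr.shape, bool)
        m[1:3, 1:3, 1:3] = True
        lv = discretize(vol, VOIMask(m, (2, 2, 2)), n_levels=4)
        assert np.all(lv.levels[~m] == 0)


class TestBuildGLCM:
    def test_1d_pair_enumeration_example(self):
        """Levels [1,1,2,2] with offset +1: P11 = P22 = 1/3, P12 = P21 = 1/6."""
        from petromics.glcm import LevelVolume

        lv_arr = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        lv = LevelVolume(lv_arr, 2, (0.0, 1.0))
        M = build_glcm(lv, offsets=((1, 0, 0),), symmetric=True)
        np.testing.assert_allclose(
            M.P, [[1 / 3, 1 / 6], [1 / 6, 1 / 3]], atol=1e-15
        )

    def test_constant_volume_single_cell(self):
        from petromics.glcm import LevelVolume

        lv = LevelVolume(np.ones((3, 3, 3), int), 4, (0.0, 0.0))
        M = build_glcm(lv)
        assert M.P[0, 0] == pytest.approx(1.0)

    def test_checkerboard_has_no_like_neighbors(self):
        from petromics.glcm import LevelVolume

        idx = np.indices((4, 4, 4)).sum(axis=0)
        levels = (idx % 2) + 1
        lv = LevelVolume(levels, 2, (0.0, 1.0))
        M = build_glcm(lv, offsets=((1, 0, 0), (0, 1, 0), (0, 0, 1)))
        assert M.P[0, 0] == 0.0 and M.P[1, 1] == 0.0

    def test_single_voxel_mask_rejected(self):
        from petromics.glcm import LevelVolume

        levels = np.zeros((3, 3, 3), int)
        levels[1, 1, 1] = 1
        with pytest.raises(DataError, match="empty GLCM"):
            build_glcm(LevelVolume(levels, 2, (0.0, 1.0)))


class TestGLCMFeatures:
    def test_degenerate_single_level(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = glcm_features(GLCMMatrix(P, ((1, 0, 0),)))
        assert f.contrast == 0.0
        assert f.energy == 1.0
        assert f.homogeneity == 1.0
        assert np.isnan(f.correlation) and "zero marginal" in f.correlation_note

    def test_worked_2x2_example(self):
        P = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        f = glcm_features(GLCMMatrix(P, ((1, 0, 0),)))
        assert f.contrast == pytest.approx(1 / 3, rel=1e-12)
        assert f.energy == pytest.approx(2 / 9 + 2 / 36, rel=1e-12)
        assert f.homogeneity == pytest.approx(2 / 3 + 1 / 6, rel=1e-12)
        assert f.correlation == pytest.approx(1 / 3, rel=1e-12)

    def test_uniform_matrix_energy_is_inverse_cells(self):
        G = 6
        P = np.full((G, G), 1.0 / G**2)
        f = glcm_features(GLCMMatrix(P, ((1, 0, 0),)))
        assert f.energy == pytest.approx(1.0 / G**2, rel=1e-12)

    def test_diagonal_matrix_iff_zero_contrast_unit_homogeneity(self):
        P = np.diag([0.25, 0.5, 0.25])
        f = glcm_features(GLCMMatrix(P, ((1, 0, 0),)))
        assert f.contrast == 0.0 and f.homogeneity == pytest.approx(1.0)
        Q = P.copy()
        Q[0, 1] = Q[1, 0] = 0.1
        Q /= Q.sum()
        g = glcm_features(GLCMMatrix(Q, ((1, 0, 0),)))
        assert g.contrast > 0.0 and g.homogeneity < 1.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode,offsets", [("3d", OFFSETS_3D), ("2d", OFFSETS_2D_AXIAL)])
    def test_200_random_masks_match_exhaustive_enumeration(self, mode, offsets):
        """Pipeline GLCM features equal the brute-force oracle to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = tuple(rng.integers(2, 7, 3))
            G = int(rng.integers(2, 9))
            mask = rng.random(shape) < 0.7
            if mask.sum() < 2:
                continue
            vals = rng.uniform(0, 10, shape)
            vol = pm.SUVVolume(vals, (2, 2, 2))
            try:
                voi = VOIMask(mask, (2, 2, 2))
                lv = discretize(vol, voi, n_levels=G)
                M = build_glcm(lv, offsets=offsets, symmetric=True)
            except DataError:
                continue
            counts = glcm_counts_oracle(lv.levels, offsets, symmetric=True)
            P_oracle = np.zeros((G, G))
            P_oracle[: counts.shape[0], : counts.shape[1]] = counts / counts.sum()
            np.testing.assert_allclose(M.P, P_oracle, atol=1e-12)
            c, r, e, h = glcm_features_oracle(M.P)
            f = glcm_features(M)
            assert f.contrast == pytest.approx(c, abs=1e-12)
            assert f.energy == pytest.approx(e, abs=1e-12)
            assert f.homogeneity == pytest.approx(h, abs=1e-12)
            if not np.isnan(f.correlation):
                assert f.correlation == pytest.approx(r, abs=1e-12)


class TestLevelPermutationSensitivity:
    def test_only_energy_is_permutation_invariant(self):
        """Contrast/correlation/homogeneity read level order; energy does not."""
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 10, (5, 5, 5))
        vol, mask = _volume_mask(vals)
        lv = discretize(vol, mask, n_levels=4)
        M = build_glcm(lv)
        f = glcm_features(M)
        from petromics.glcm import LevelVolume

        perm = np.array([0, 3, 1, 4, 2])  # relabel levels 1->3, 2->1, 3->4, 4->2
        permuted = LevelVolume(perm[lv.levels], 4, lv.discretization_range)
        g = glcm_features(build_glcm(permuted))
        assert g.energy == pytest.approx(f.energy, rel=1e-12)
        assert g.contrast != pytest.approx(f.contrast, rel=1e-6)
        assert g.homogeneity != pytest.approx(f.homogeneity, rel=1e-6)


class TestTexturePipeline:
    def test_homogeneity_trend_with_texture_correlation_length(self):
        """Smoother tumors do not read as less homogeneous (20-seed means)."""
        means = []
        for clen in (3.0, 12.0):
            vals = []
            for seed in range(20):
                vol, truth = pm.generate_phantom(
                    pm.PhantomSpec(texture_corr_len=clen), seed
                )
                f = pm.extract_features(vol, truth.true_mask.bounding_box(3))
                vals.append(f["glcm_homogeneity"])
            means.append(np.mean(vals))
        assert means[1] >= means[0] - 1e-9

    def test_mode_and_level_knobs_change_output(self):
        vol, truth = pm.generate_phantom(pm.PhantomSpec(), 0)
        region = truth.true_mask.bounding_box(3)
        f8 = pm.extract_features(vol, region, pm.PipelineConfig(glcm_levels=8))
        f64 = pm.extract_features(vol, region, pm.PipelineConfig(glcm_levels=64))
        f2d = pm.extract_features(
            vol, region, pm.PipelineConfig(glcm_mode="2d-axial")
        )
        assert f8["glcm_contrast"] != f64["glcm_contrast"]
        assert f8["glcm_contrast"] != f2d["glcm_contrast"]
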
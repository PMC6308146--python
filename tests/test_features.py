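"""Shape, first-order and texture features against hand values and
brute-force oracles."""

import numpy as np
import pytest

from npcradiomics import (
    ImageVolume,
    RoiMask,
    first_order_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    normalize_and_quantize,
    shape_features,
)
from npcradiomics.features.texture import _glcm_dir_features, _glcm_matrix
from npcradiomics.preprocess import QuantizedRoi

from oracles import (
    oracle_first_order,
    oracle_glcm,
    oracle_gldm,
    oracle_glrlm,
    oracle_glszm,
    oracle_ngtdm,
)


def _ball_mask(shape, spacing, radius_mm):
    coords = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return RoiMask(x**2 + y**2 + z**2 <= radius_mm**2, spacing)


def _qroi_from_levels(levels, n_levels=64):
    levels = np.asarray(levels, dtype=np.int64)
    inc = levels[levels > 0].astype(float)
    return QuantizedRoi(levels, inc, float(inc.mean()), float(inc.std()), 0, n_levels, (1, 1, 1))


class TestShape:
    def test_digital_ball_matches_analytic_sphere(self):
        r = 10.0
        mask = _ball_mask((27, 27, 27), (1.0, 1.0, 1.0), r)
        f = shape_features(mask)
        assert f["shape_Volume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)
        assert 0.97 <= f["shape_Sphericity"] <= 1.0
        assert f["shape_Elongation"] == pytest.approx(1.0, abs=0.02)
        assert f["shape_Flatness"] == pytest.approx(1.0, abs=0.02)
        assert f["shape_Max3DDiameter"] == pytest.approx(2 * r, rel=0.05)

    def test_scaling_law(self):
        small = shape_features(_ball_mask((15, 15, 15), (1.0, 1.0, 1.0), 5.0))
        big = shape_features(_ball_mask((27, 27, 27), (1.0, 1.0, 1.0), 10.0))
        assert big["shape_Volume"] == pytest.approx(8 * small["shape_Volume"], rel=0.03)
        assert big["shape_SurfaceArea"] == pytest.approx(
            4 * small["shape_SurfaceArea"], rel=0.03
        )

    def test_single_voxel_degenerate_axes_warn(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        with pytest.warns(UserWarning):
            f = shape_features(RoiMask(m, (1.0, 1.0, 1.0)))
        assert f["shape_MajorAxisLength"] == 0.0
        assert f["shape_Elongation"] == 0.0


class TestFirstOrder:
    def test_hand_arithmetic_1234(self):
        levels = np.zeros((1, 1, 4), dtype=np.int64)
        levels[0, 0, :] = [1, 2, 3, 4]
        q = QuantizedRoi(levels, np.array([1.0, 2.0, 3.0, 4.0]), 2.5, 0.0, 0, 64, (1, 1, 1))
        f = first_order_features(q)
        assert f["F_RMS"] == pytest.approx(np.sqrt(30 / 4))
        assert f["F_Variance"] == pytest.approx(1.25)
        assert f["F_Mean"] == pytest.approx(2.5)

    def test_constant_roi_degenerate_conventions(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        q = QuantizedRoi(levels, np.full(27, 7.0), 7.0, 0.0, 0, 64, (1, 1, 1))
        f = first_order_features(q)
        assert f["F_Mean"] == 7.0 and f["F_RMS"] == 7.0
        assert f["F_Variance"] == 0.0 and f["F_Entropy"] == 0.0
        assert f["F_Uniformity"] == 1.0

    def test_symmetric_distribution_has_zero_skewness(self, rng):
        x = rng.normal(size=100_000)
        levels = np.ones((100, 100, 10), dtype=np.int64)
        q = QuantizedRoi(levels, x, 0.0, 1.0, 0, 64, (1, 1, 1))
        assert abs(first_order_features(q)["F_Skew"]) < 0.05

    def test_matches_oracle_on_random_roi(self, make_qroi):
        q = make_qroi(seed=5)
        f = first_order_features(q)
        o = oracle_first_order(q.included_values, q.level_histogram())
        for k, v in o.items():
            assert f[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k


class TestGlcm:
    def test_constant_roi_single_cell(self):
        q = _qroi_from_levels(np.full((4, 4, 4), 3))
        f = glcm_features(q)
        assert f["glcm_JEN"] == pytest.approx(0.0, abs=1e-12)
        assert f["glcm_MP"] == 1.0
        assert f["glcm_Contrast"] == 0.0

    def test_checkerboard_axis_offset_contrast(self):
        """4x4x1 checkerboard of levels {1, 2}: along an axis offset all
        co-occurrence mass sits on (1,2)/(2,1), so contrast = 1."""
        board = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        P = _glcm_matrix(board, (1, 0, 0), 64)
        assert P[0, 1] + P[1, 0] == pytest.approx(1.0)
        f = _glcm_dir_features(P, 64)
        assert f["glcm_Contrast"] == pytest.approx(1.0)
        o = oracle_glcm(board, 64)  # full 13-direction average also agrees
        fa = glcm_features(_qroi_from_levels(board))
        for k in fa:
            assert fa[k] == pytest.approx(o[k], rel=1e-10, abs=1e-12), k

    def test_offset_order_irrelevant(self, make_qroi):
        # averaging over directions is commutative; feature values are
        # independent of the order in which offsets are visited
        q = make_qroi(seed=3)
        assert glcm_features(q) == glcm_features(q)


class TestTextureOracles:
    FAMILIES = [
        (glcm_features, oracle_glcm),
        (glrlm_features, oracle_glrlm),
        (glszm_features, oracle_glszm),
        (gldm_features, oracle_gldm),
        (ngtdm_features, oracle_ngtdm),
    ]

    @pytest.mark.parametrize("impl,oracle", FAMILIES, ids=lambda f: f.__name__)
    def test_random_roi_matches_brute_force(self, impl, oracle, make_qroi):
        for seed in range(3):
            q = make_qroi(seed=seed)
            f = impl(q)
            o = oracle(q.level_grid, q.n_levels)
            for k, v in o.items():
                assert f[k] == pytest.approx(v, rel=1e-10, abs=1e-12), (seed, k)

    def test_glszm_hand_built_zones(self):
        levels = np.array([[[1], [1], [2]], [[2], [2], [3]], [[3], [3], [3]]])
        f = glszm_features(_qroi_from_levels(levels))
        # zones under 26-connectivity: level 1 size 2, level 2 size 3, level 3 size 4
        assert f["glszm_ZP"] == pytest.approx(3 / 9)
        assert f["glszm_SAE"] == pytest.approx((1 / 4 + 1 / 9 + 1 / 16) / 3)
        assert f["glszm_LAE"] == pytest.approx((4 + 9 + 16) / 3)
        o = oracle_glszm(levels, 64)
        for k, v in o.items():
            assert f[k] == pytest.approx(v, rel=1e-12), k

    def test_constant_roi_homogeneous_conventions(self):
        q = _qroi_from_levels(np.full((3, 3, 3), 5))
        assert ngtdm_features(q)["ngtdm_Complexity"] == 0.0
        rl = glrlm_features(q)
        assert rl["glrlm_GLNN"] == pytest.approx(1.0)  # single gray level
        o = oracle_glrlm(q.level_grid, 64)
        assert rl["glrlm_RLN"] == pytest.approx(o["glrlm_RLN"], rel=1e-12)


class TestTextureInvariances:
    def test_affine_rescaling_leaves_texture_unchanged(self, rng):
        base = rng.normal(size=(10, 10, 10))
        mask = RoiMask(np.ones(base.shape, bool), (1.0, 1.0, 1.0))
        q1 = normalize_and_quantize(ImageVolume(base, (1, 1, 1)), mask)
        q2 = normalize_and_quantize(ImageVolume(5.0 * base - 3.0, (1, 1, 1)), mask)
        f1, f2 = glcm_features(q1), glcm_features(q2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_translation_of_roi_within_grid(self, make_qroi):
        q = make_qroi(seed=11, shape=(8, 8, 8))
        shifted = np.zeros((12, 12, 12), dtype=np.int64)
        shifted[2:10, 1:9, 3:11] = q.level_grid
        q2 = QuantizedRoi(
            shifted, q.included_values, q.m, q.s, 0, q.n_levels, q.spacing_mm
        )
        for impl in (glcm_features, glrlm_features, glszm_features, gldm_features,
                     ngtdm_features):
            f1, f2 = impl(q), impl(q2)
            for k in f1:
                assert f1[k] == pytest.approx(f2[k], rel=1e-12), k
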
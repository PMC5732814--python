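import numpy as np
import pytest

from radsurv.imaging import QuantizedROI
from radsurv.texture import (
    GLCM,
    GLZM,
    compute_glcm,
    compute_glzm,
    compute_ngtdm,
    extract_texture,
    glcm_features,
    glzm_features,
    ngtdm_features,
    TEXTURE_FEATURE_NAMES,
)

from _oracles import brute_glcm, brute_glzm, brute_ngtdm
from conftest import random_quantized


def constant_roi(shape=(3, 3, 3), level=2, ng=4) -> QuantizedROI:
    return QuantizedROI(data=np.full(shape, level, dtype=np.int32), n_levels=ng)


class TestGLCM:
    def test_constant_roi_single_cell(self):
        M = compute_glcm(constant_roi(level=3))
        assert M.P[2, 2] == pytest.approx(1.0)
        assert M.P.sum() == pytest.approx(1.0)

    def test_single_pair_symmetrized(self):
        q = QuantizedROI(data=np.array([[[1, 2]]], dtype=np.int32), n_levels=2)
        M = compute_glcm(q, symmetric=True)
        assert M.P[0, 1] == pytest.approx(0.5)
        assert M.P[1, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_pair_enumeration(self, seed, symmetric):
        rng = np.random.default_rng(seed)
        q = random_quantized(rng, shape=(4, 4, 4), ng=4)
        M = compute_glcm(q, symmetric=symmetric)
        _, P_ref = brute_glcm(q.data, ng=4, symmetric=symmetric)
        np.testing.assert_allclose(M.P, P_ref, atol=1e-12)

    def test_background_excluded(self):
        data = np.zeros((3, 1, 1), dtype=np.int32)
        data[0, 0, 0] = 1
        data[2, 0, 0] = 2  # separated by background: no adjacent pair at d=1
        q = QuantizedROI(data=data, n_levels=2)
        with pytest.raises(ValueError, match="pairs"):
            compute_glcm(q)

    def test_distance_two_skips_immediate_neighbors(self):
        q = QuantizedROI(data=np.array([[[1, 2, 1]]], dtype=np.int32), n_levels=2)
        M = compute_glcm(q, distance=2)
        assert M.P[0, 0] == pytest.approx(1.0)  # only the (1, ., 1) pair


class TestGLCMFeatures:
    def test_degenerate_single_cell(self):
        M = compute_glcm(constant_roi(level=2))
        f = glcm_features(M)
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_entropy"] == pytest.approx(0.0)
        assert f["glcm_contrast"] == pytest.approx(0.0)
        assert f["glcm_dissimilarity"] == pytest.approx(0.0)
        assert f["glcm_homogeneity"] == pytest.approx(1.0)
        assert f["glcm_correlation"] == 0.0  # zero-variance marginal convention

    def test_uniform_two_level_hand_sums(self):
        # P uniform over levels {1,2}: contrast = dissimilarity = 0.5, energy = 0.25
        P = np.full((2, 2), 0.25)
        f = glcm_features(GLCM(P=P, n_levels=2, offsets=(), symmetric=True))
        assert f["glcm_contrast"] == pytest.approx(0.5)
        assert f["glcm_dissimilarity"] == pytest.approx(0.5)
        assert f["glcm_energy"] == pytest.approx(0.25)
        assert f["glcm_entropy"] == pytest.approx(2.0)
        assert f["glcm_autocorrelation"] == pytest.approx(0.25 * (1 + 2 + 2 + 4))

    def test_correlation_bounded_on_random_symmetric_matrices(self, rng):
        for _ in range(50):
            ng = int(rng.integers(2, 6))
            A = rng.random((ng, ng))
            P = (A + A.T) / (A + A.T).sum()
            f = glcm_features(GLCM(P=P, n_levels=ng, offsets=(), symmetric=True))
            assert -1.0 - 1e-9 <= f["glcm_correlation"] <= 1.0 + 1e-9


class TestNGTDM:
    def test_constant_roi_zero_differences(self):
        T = compute_ngtdm(constant_roi())
        assert T.s.sum() == pytest.approx(0.0)
        assert T.n_counted == 27

    def test_center_ring_hand_enumeration(self):
        # 3x3x1 plate: center level 2, ring level 1
        data = np.ones((3, 3, 1), dtype=np.int32)
        data[1, 1, 0] = 2
        T = compute_ngtdm(QuantizedROI(data=data, n_levels=2))
        # center: all 8 in-plane neighbors are level 1 -> |2 - 1| = 1
        assert T.s[1] == pytest.approx(1.0)
        # corner ring voxel: neighbors are 2 edge voxels (level 1) + center (2)
        # -> |1 - 4/3| = 1/3; edge ring voxel: 4 ring + center -> |1 - 6/5| = 1/5
        assert T.s[0] == pytest.approx(4 * (1 / 3) + 4 * (1 / 5))
        assert T.n.tolist() == [8, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = random_quantized(rng, shape=(5, 4, 3), ng=4)
        T = compute_ngtdm(q)
        s_ref, n_ref = brute_ngtdm(q.data, ng=4)
        np.testing.assert_allclose(T.s, s_ref, atol=1e-10)
        np.testing.assert_array_equal(T.n, n_ref)


class TestNGTDMFeatures:
    def test_constant_roi_degenerate_values(self):
        f = ngtdm_features(compute_ngtdm(constant_roi()))
        assert f["ngtdm_coarseness"] == pytest.approx(1e12)  # capped at 1/eps
        assert f["ngtdm_contrast"] == 0.0
        assert f["ngtdm_strength"] == 0.0

    def test_checkerboard_matches_direct_formula_evaluation(self):
        x, y, z = np.indices((4, 4, 4))
        data = (1 + (x + y + z) % 2).astype(np.int32)
        T = compute_ngtdm(QuantizedROI(data=data, n_levels=2))
        s, n = T.s, T.n
        p = n / n.sum()
        N = int(n.sum())
        f = ngtdm_features(T)
        assert f["ngtdm_coarseness"] == pytest.approx(1.0 / (1e-12 + (p * s).sum()))
        pair = p[0] * p[1] * (1 - 2) ** 2 * 2
        assert f["ngtdm_contrast"] == pytest.approx(pair / 2 * (s.sum() / N))
        denom = 2 * abs(1 * p[0] - 2 * p[1])
        assert f["ngtdm_busyness"] == pytest.approx((p * s).sum() / denom)

    def test_coarseness_inverse_in_s_scale(self):
        rng = np.random.default_rng(3)
        q = random_quantized(rng, shape=(5, 5, 5), ng=4)
        T = compute_ngtdm(q)
        base = ngtdm_features(T)["ngtdm_coarseness"]
        from radsurv.texture import NGTDM

        scaled = ngtdm_features(
            NGTDM(s=3.0 * T.s, n=T.n, p=T.p, n_levels=T.n_levels, n_counted=T.n_counted)
        )["ngtdm_coarseness"]
        assert scaled == pytest.approx(base / 3.0, rel=1e-6)


class TestGLZM:
    def test_constant_cube_single_zone(self):
        Z = compute_glzm(constant_roi(level=2, ng=4))
        assert Z.n_zones == 1
        assert Z.P[1, 26] == 1  # one zone of 27 voxels at level 2

    def test_diagonal_voxels_joined_under_26_connectivity(self):
        data = np.zeros((2, 2, 2), dtype=np.int32)
        data[0, 0, 0] = data[1, 1, 1] = 1
        Z = compute_glzm(QuantizedROI(data=data, n_levels=1))
        assert Z.n_zones == 1
        assert Z.P[0, 1] == 1  # single zone of size 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        q = random_quantized(rng, shape=(5, 5, 5), ng=3)
        Z = compute_glzm(q)
        P_ref = brute_glzm(q.data, ng=3)
        np.testing.assert_array_equal(Z.P, P_ref)

    def test_mass_conservation_exact(self, rng):
        for _ in range(20):
            q = random_quantized(rng, shape=(6, 5, 4), ng=4)
            Z = compute_glzm(q)
            z = np.arange(1, Z.P.shape[1] + 1)
            assert int((Z.P * z[None, :]).sum()) == int(q.mask.sum())
            assert int(Z.P.sum()) == Z.n_zones


class TestGLZMFeatures:
    def test_single_zone_closed_form(self):
        P = np.zeros((4, 27), dtype=np.int64)
        P[2, 26] = 1  # level 3, size 27
        f = glzm_features(GLZM(P=P, n_levels=4, n_zones=1, n_voxels=27))
        assert f["glzm_grey_level_nonuniformity"] == pytest.approx(1.0)
        assert f["glzm_zone_size_nonuniformity"] == pytest.approx(1.0)
        assert f["glzm_zone_percentage"] == pytest.approx(1 / 27)
        assert f["glzm_large_zone_high_grey_emphasis"] == pytest.approx(9 * 27**2)

    def test_all_singleton_zones(self):
        # checkerboard-like: every voxel its own zone
        P = np.zeros((2, 1), dtype=np.int64)
        P[0, 0] = 5
        P[1, 0] = 5
        f = glzm_features(GLZM(P=P, n_levels=2, n_zones=10, n_voxels=10))
        assert f["glzm_zone_percentage"] == pytest.approx(1.0)
        assert f["glzm_small_zone_emphasis"] == pytest.approx(1.0)

    def test_random_matrix_matches_direct_summation(self, rng):
        P = rng.integers(0, 4, size=(3, 6)).astype(np.int64)
        P[0, 0] += 1
        nz = int(P.sum())
        nv = int((P * np.arange(1, 7)[None, :]).sum())
        f = glzm_features(GLZM(P=P, n_levels=3, n_zones=nz, n_voxels=nv))
        sze = sum(P[i, z] / (z + 1) ** 2 for i in range(3) for z in range(6)) / nz
        lzhge = sum(
            P[i, z] * (i + 1) ** 2 * (z + 1) ** 2 for i in range(3) for z in range(6)
        ) / nz
        assert f["glzm_small_zone_emphasis"] == pytest.approx(sze)
        assert f["glzm_large_zone_high_grey_emphasis"] == pytest.approx(lzhge)


class TestExtractTexture:
    def test_full_vector_finite_for_constant_roi(self):
        f = extract_texture(constant_roi())
        assert set(f) == set(TEXTURE_FEATURE_NAMES)
        assert all(np.isfinite(v) for v in f.values())
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glzm_grey_level_nonuniformity"] == pytest.approx(1.0)

    def test_deterministic(self, rng):
        q = random_quantized(rng, shape=(6, 6, 6), ng=4)
        assert extract_texture(q) == extract_texture(q)

    def test_axis_permutation_invariance(self, rng):
        q = random_quantized(rng, shape=(5, 6, 7), ng=4)
        f0 = extract_texture(q)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            qp = QuantizedROI(data=np.transpose(q.data, perm), n_levels=q.n_levels)
            fp = extract_texture(qp)
            for name in f0:
                assert fp[name] == pytest.approx(f0[name], rel=1e-9), name

    def test_matches_per_family_recomputation(self, rng):
        q = random_quantized(rng, shape=(5, 5, 5), ng=4)
        f = extract_texture(q)
        assert f["glcm_contrast"] == glcm_features(compute_glcm(q))["glcm_contrast"]
        assert f["ngtdm_busyness"] == ngtdm_features(compute_ngtdm(q))["ngtdm_busyness"]
        assert f["glzm_zone_percentage"] == glzm_features(compute_glzm(q))["glzm_zone_percentage"]
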
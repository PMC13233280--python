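import numpy as np
import pytest

from deltarad.features import (extract_all, first_order_features,
                               glcm_features, glcm_matrix, glrlm_features,
                               glszm_features, ngtdm_features, roi_volume)
from deltarad.preprocess import DegenerateROIError, ImageVolume, ROIMask
from deltarad.registry import adjusted_registry, default_registry

from .conftest import make_droi, random_droi
from . import oracles


class TestFirstOrder:
    def test_symmetric_values_have_zero_skewness(self):
        d = make_droi(np.array([1, 2, 3]).reshape(3, 1, 1))
        out = first_order_features(d, np.array([1.0, 2.0, 3.0]))
        assert out["Global Skewness"] == pytest.approx(0.0, abs=1e-14)

    def test_skewness_matches_direct_moment_sum(self):
        x = np.array([1.0, 1.0, 1.0, 10.0])
        d = make_droi(np.array([1, 1, 1, 4]).reshape(4, 1, 1))
        out = first_order_features(d, x)
        mu = x.mean()
        sd = np.sqrt(((x - mu) ** 2).mean())
        expected = ((x - mu) ** 3).mean() / sd ** 3
        assert out["Global Skewness"] == pytest.approx(expected, rel=1e-12)

    def test_constant_roi_convention(self):
        d = make_droi(np.ones((2, 2, 2), int))
        out = first_order_features(d, np.full(8, 5.0))
        assert out["Global Variance"] == 0.0
        assert out["Global Skewness"] == 0.0
        assert out["Global Kurtosis"] == 0.0
        assert out["Global Entropy"] == 0.0


class TestGLCM:
    def test_constant_roi_homogeneity_one_contrast_zero(self):
        d = make_droi(np.ones((2, 2, 1), int))
        out = glcm_features(d)
        assert out["GLCM Homogeneity"] == pytest.approx(1.0)
        assert out["GLCM Contrast"] == pytest.approx(0.0)

    def test_2d_slab_matches_hand_enumerated_pairs(self):
        # levels [[1,2],[1,2]] in a single slice, in-plane offsets only
        levels = np.array([[1, 2], [1, 2]]).reshape(2, 2, 1)
        d = make_droi(levels)
        inplane = [(0, 1, 0), (1, 0, 0), (1, 1, 0), (1, -1, 0)]
        mat = glcm_matrix(d, inplane)
        oracle = oracles.glcm_oracle(levels, 2, inplane)
        np.testing.assert_array_equal(mat, oracle)
        ours = glcm_features(d, inplane)
        ref = oracles.glcm_features_oracle(levels, 2, inplane)
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, rel=1e-12), k

    def test_checkerboard_maximizes_contrast(self, rng):
        shape = (4, 4, 4)
        idx = np.indices(shape).sum(axis=0)
        checker = 1 + (idx % 2)
        d_checker = make_droi(checker)
        c_max = glcm_features(d_checker)["GLCM Contrast"]
        for _ in range(30):
            other = make_droi(rng.integers(1, 3, size=shape))
            assert glcm_features(other)["GLCM Contrast"] <= c_max + 1e-12

    def test_matrix_is_symmetric_and_normalizes(self, rng):
        d = random_droi(rng)
        mat = glcm_matrix(d)
        np.testing.assert_array_equal(mat, mat.T)


class TestGLRLM:
    def test_single_run_lre(self):
        levels = np.ones((1, 1, 4), int)
        d = make_droi(levels)
        out = glrlm_features(d, offsets=[(0, 0, 1)])
        assert out["GLRLM LRE"] == pytest.approx(16.0)
        assert out["GLRLM SRE"] == pytest.approx(1 / 16)

    def test_alternating_levels_all_singleton_runs(self):
        levels = np.array([1, 2, 1, 2]).reshape(1, 1, 4)
        d = make_droi(levels)
        out = glrlm_features(d, offsets=[(0, 0, 1)])
        assert out["GLRLM SRE"] == pytest.approx(1.0)
        assert out["GLRLM LRE"] == pytest.approx(1.0)


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        levels = np.ones((2, 3, 2), int)
        d = make_droi(levels)
        out = glszm_features(d)
        assert out["GLSZM ZP"] == pytest.approx(1 / 12)
        assert out["GLSZM LAE"] == pytest.approx(144.0)

    def test_all_distinct_levels_all_singleton_zones(self):
        levels = np.arange(1, 9).reshape(2, 2, 2)
        d = make_droi(levels)
        out = glszm_features(d)
        assert out["GLSZM SAE"] == pytest.approx(1.0)
        assert out["GLSZM ZP"] == pytest.approx(1.0)


class TestNGTDM:
    def test_constant_roi_coarseness_cap(self):
        d = make_droi(np.ones((3, 3, 3), int))
        out = ngtdm_features(d)
        assert out["NGTDM Coarseness"] == 1e6
        assert out["NGTDM Contrast"] == 0.0

    def test_center_voxel_hand_computation(self):
        levels = np.ones((3, 3, 1), int)
        levels[1, 1, 0] = 2
        d = make_droi(levels)
        # level 2 center: 8 neighbors all level 1 -> s_2 = 1
        # each level-1 voxel sees the center plus other ones
        from deltarad.features import ngtdm_table
        n_g, s_g, nvc = ngtdm_table(d)
        assert nvc == 9
        assert s_g[1] == pytest.approx(1.0)
        # corner voxels: neighbors {1,1,2} -> mean 4/3, diff 1/3 (x4)
        # edge voxels: neighbors {1,1,1,1,2} -> mean 6/5, diff 1/5 (x4)
        assert s_g[0] == pytest.approx(4 * (1 / 3) + 4 * (1 / 5), rel=1e-12)


class TestOracleEquivalence:
    """Vectorized features equal exhaustive enumeration on random small ROIs."""

    N_TRIALS = 120

    def test_all_families_match_brute_force(self, rng):
        for trial in range(self.N_TRIALS):
            d = random_droi(rng, ng=4, max_shape=5)
            lv = d.levels
            ours = {}
            ours.update(glcm_features(d))
            ours.update(glrlm_features(d))
            ours.update(glszm_features(d))
            ours.update(ngtdm_features(d))
            ref = {}
            ref.update(oracles.glcm_features_oracle(lv, d.Ng))
            ref.update(oracles.glrlm_features_oracle(lv, d.Ng, d.n_voxels))
            ref.update(oracles.glszm_features_oracle(lv, d.Ng, d.n_voxels))
            ref.update(oracles.ngtdm_features_oracle(lv, d.Ng))
            for name, expected in ref.items():
                got = ours[name]
                assert got == pytest.approx(expected, rel=1e-10, abs=1e-12), \
                    f"trial {trial}: {name}"

    def test_translation_invariance(self, rng):
        d = random_droi(rng, ng=4, max_shape=4)
        padded = np.zeros((8, 8, 8), dtype=np.int64)
        padded[1:1 + d.levels.shape[0], 2:2 + d.levels.shape[1],
               3:3 + d.levels.shape[2]] = d.levels
        d2 = make_droi(padded)
        d2.Ng = d.Ng
        for fn in (glcm_features, glrlm_features, glszm_features, ngtdm_features):
            a, b = fn(d), fn(d2)
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-12), k


class TestGeometryAndExtractAll:
    def test_roi_volume_scales_with_spacing(self):
        mask = np.zeros((5, 5, 5), bool)
        mask.reshape(-1)[:10] = True
        m = ROIMask(mask)
        assert roi_volume(m, (1.0, 1.0, 1.0)) == pytest.approx(10.0)
        assert roi_volume(m, (2.0, 2.0, 2.0)) == pytest.approx(80.0)

    def _skewed_image(self, shape_param=5.0, seed=11):
        from scipy import stats
        shape = (36, 36, 36)
        idx = np.indices(shape, dtype=float)
        c = [(n - 1) / 2 for n in shape]
        q = sum(((idx[k] - c[k]) / s) ** 2 for k, s in zip(range(3), (16, 14, 12)))
        mask = q <= 1
        rng = np.random.default_rng(seed)
        vox = rng.normal(10, 2, shape)
        vox[mask] = stats.skewnorm.rvs(shape_param, loc=50, scale=10,
                                       size=int(mask.sum()), random_state=rng)
        return ImageVolume(vox, (1.0, 1.0, 1.0)), ROIMask(mask)

    def test_extract_all_returns_full_registry(self):
        img, mask = self._skewed_image()
        fv = extract_all(img, mask)
        assert list(fv.values) == default_registry().names
        assert len(fv.values) == 43
        assert fv.values["Geometry Volume"] > 0

    def test_extract_all_is_deterministic(self):
        img, mask = self._skewed_image()
        a = extract_all(img, mask)
        b = extract_all(img, mask)
        assert a.values == b.values

    def test_skewness_recovers_sample_skewness(self):
        img, mask = self._skewed_image(shape_param=5.0)
        x = img.voxels[mask.voxels]
        assert x.size > 1e4
        mu, sd = x.mean(), x.std()
        direct = ((x - mu) ** 3).mean() / sd ** 3
        fv = extract_all(img, mask)
        assert fv.values["Global Skewness"] == pytest.approx(direct, abs=0.1)

    def test_degenerate_roi_error_carries_context(self):
        img = ImageVolume(np.ones((4, 4, 4)), (1.0, 1.0, 1.0))
        mask_arr = np.zeros((4, 4, 4), bool)
        mask_arr[0, 0, 0] = True
        with pytest.raises(DegenerateROIError, match="patient=P9"):
            extract_all(img, ROIMask(mask_arr), patient_id="P9", fraction=3)

    def test_adjusted_registry_names_cover_reported_predictors(self):
        names = adjusted_registry().names
        for required in ["Global Skewness", "GLCM Homogeneity", "GLRLM LRE",
                         "GLRLM RLV", "GLRLM LGRE", "GLRLM SRLGE", "GLRLM SRHGE",
                         "GLSZM LGZE", "Geometry Volume", "GLRLM RLN-VN",
                         "GLRLM GLN-VN", "GLSZM GLN-VN", "GLSZM ZSN-VN",
                         "NGTDM Coarseness-VNF", "NGTDM Busyness-VNF",
                         "NGTDM Strength-VN"]:
            assert required in names
        assert len(names) == 43
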
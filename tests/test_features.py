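"""First-order, GLCM, GLRLM and wavelet feature computations.

The GLCM/GLRLM routes are dual-checked against brute-force oracles
(exhaustive enumeration with explicit loops) on random small patches.
"""

import numpy as np
import pytest

from conftest import random_patch
from oracles import (
    glcm_bruteforce,
    glcm_features_bruteforce,
    glrlm_bruteforce,
    glrlm_features_bruteforce,
)
from usradiomics.features import (
    DegenerateMatrixError,
    TextureMatrix,
    dwt2_subbands,
    extract_all,
    first_order,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    wavelet_subbands,
)
from usradiomics.roi import RoiPatch

ANGLES = (0, 45, 90, 135)


def full_patch(vals, levels=None):
    vals = np.asarray(vals, dtype=float)
    return RoiPatch(values=vals, mask=np.ones(vals.shape, dtype=bool),
                    levels=levels or int(vals.max()) + 1)


class TestFirstOrder:
    def test_constant_patch_limits(self):
        patch = full_patch(np.zeros((5, 5)), levels=256)
        with pytest.warns(UserWarning):
            f = first_order(patch)
        assert f["entropy"] == 0
        assert f["uniformity"] == 1
        assert f["variance"] == 0
        assert f["range"] == 0
        assert f["skewness"] == 0 and f["kurtosis"] == 0

    def test_two_level_histogram(self):
        vals = np.array([[0, 0, 0, 0], [255, 255, 255, 255]])
        f = first_order(full_patch(vals, levels=256))
        assert f["entropy"] == pytest.approx(1.0)       # 1 bit: two equal bins
        assert f["uniformity"] == pytest.approx(0.5)
        assert f["mean"] == pytest.approx(127.5)
        assert f["median"] == pytest.approx(127.5)

    def test_rms_variance_identity(self, rng):
        for _ in range(20):
            patch = random_patch(rng, levels=32)
            f = first_order(patch)
            assert f["root_mean_square"] ** 2 == pytest.approx(
                f["variance"] + f["mean"] ** 2, rel=1e-6)

    def test_returns_exactly_14_features(self, rng):
        assert len(first_order(random_patch(rng))) == 14


class TestGlcm:
    def test_horizontal_pairs(self):
        m = glcm(full_patch([[0, 0], [1, 1]]), angle=0)
        expect = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert np.allclose(m.matrix, expect)

    def test_vertical_pairs(self):
        m = glcm(full_patch([[0, 0], [1, 1]]), angle=90)
        expect = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert np.allclose(m.matrix, expect)

    def test_constant_patch_single_entry(self):
        m = glcm(full_patch(np.zeros((4, 4)), levels=8), angle=45)
        assert m.matrix[0, 0] == pytest.approx(1.0)
        assert m.matrix.sum() == pytest.approx(1.0)

    def test_normalization_and_symmetry(self, rng):
        for _ in range(20):
            patch = random_patch(rng)
            for angle in ANGLES:
                try:
                    m = glcm(patch, angle)
                except DegenerateMatrixError:
                    continue
                assert m.matrix.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.allclose(m.matrix, m.matrix.T)

    def test_degenerate_when_no_pairs(self):
        patch = RoiPatch(values=np.zeros((1, 3)), levels=8,
                         mask=np.array([[True, False, True]]))
        with pytest.raises(DegenerateMatrixError):
            glcm(patch, angle=0)

    def test_matches_bruteforce_on_random_patches(self, rng):
        for k in range(25):
            patch = random_patch(rng)
            vals = patch.values.astype(int).tolist()
            mask = patch.mask.tolist()
            for angle in ANGLES:
                try:
                    m = glcm(patch, angle)
                except DegenerateMatrixError:
                    continue
                oracle = np.array(glcm_bruteforce(vals, mask, angle,
                                                  levels=patch.levels))
                assert np.allclose(m.matrix, oracle, atol=1e-12)


class TestGlcmFeatures:
    def test_point_mass_limits(self):
        m = TextureMatrix("glcm", 0, np.array([[1.0]]), True)
        f = glcm_features(m)
        assert f["energy"] == 1
        assert f["entropy"] == 0
        assert f["contrast"] == 0
        assert f["maximum_probability"] == 1

    def test_two_diagonal_entries(self):
        P = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(TextureMatrix("glcm", 0, P, True))
        # p_{x+y} has two equal atoms -> 1 bit of sum entropy, no contrast
        assert f["sum_entropy"] == pytest.approx(1.0)
        assert f["contrast"] == 0

    def test_returns_exactly_22_features(self):
        f = glcm_features(glcm(full_patch([[0, 1], [2, 3]]), 0))
        assert len(f) == 22

    def test_matches_bruteforce_oracle(self, rng):
        checked = 0
        for k in range(30):
            patch = random_patch(rng)
            for angle in ANGLES:
                try:
                    m = glcm(patch, angle)
                except DegenerateMatrixError:
                    continue
                mine = glcm_features(m)
                oracle = glcm_features_bruteforce(m.matrix.tolist())
                for name, v in oracle.items():
                    assert mine[name] == pytest.approx(v, abs=1e-8), name
                checked += 1
        assert checked >= 100


class TestGlrlm:
    def test_single_run(self):
        m = glrlm(full_patch([[5, 5, 5, 5]], levels=8), angle=0)
        assert m.matrix[5, 3] == 1        # one run of level 5, length 4
        assert m.matrix.sum() == 1

    def test_two_runs(self):
        m = glrlm(full_patch([[1, 1, 2, 2]], levels=8), angle=0)
        assert m.matrix[1, 1] == 1 and m.matrix[2, 1] == 1
        assert m.matrix.sum() == 2

    def test_mask_gap_breaks_runs(self):
        patch = RoiPatch(values=np.array([[3.0, 3, 3, 3, 3]]), levels=8,
                         mask=np.array([[True, True, False, True, True]]))
        m = glrlm(patch, angle=0)
        assert m.matrix[3, 1] == 2  # two runs of length 2

    def test_pixel_conservation_all_angles(self, rng):
        for _ in range(20):
            patch = random_patch(rng)
            for angle in ANGLES:
                m = glrlm(patch, angle)
                g, r = np.nonzero(m.matrix)
                assert (m.matrix[g, r] * (r + 1)).sum() == patch.mask.sum()

    def test_matches_bruteforce_on_random_patches(self, rng):
        for k in range(25):
            patch = random_patch(rng)
            vals = patch.values.astype(int).tolist()
            mask = patch.mask.tolist()
            for angle in ANGLES:
                m = glrlm(patch, angle)
                runs = glrlm_bruteforce(vals, mask, angle)
                dense = np.zeros_like(m.matrix)
                for (g, r), n in runs.items():
                    dense[g, r - 1] = n
                assert np.array_equal(m.matrix[:, :dense.shape[1]],
                                      dense[:, :m.matrix.shape[1]])


class TestGlrlmFeatures:
    def test_all_runs_length_one(self):
        board = np.indices((6, 6)).sum(axis=0) % 2  # checkerboard
        m = glrlm(full_patch(board, levels=2), angle=0)
        f = glrlm_features(m)
        assert f["short_run_emphasis"] == 1
        assert f["long_run_emphasis"] == 1
        assert f["run_percentage"] == 1

    def test_single_long_run(self):
        M = np.zeros((8, 8))
        M[5, 3] = 1  # one run of length 4
        f = glrlm_features(TextureMatrix("glrlm", 0, M, False, n_pixels=4))
        assert f["long_run_emphasis"] == pytest.approx(16.0)
        assert f["short_run_emphasis"] == pytest.approx(1 / 16.0)

    def test_zero_runs_degenerate(self):
        M = np.zeros((4, 4))
        with pytest.raises(DegenerateMatrixError):
            glrlm_features(TextureMatrix("glrlm", 0, M, False, n_pixels=1))

    def test_matches_bruteforce_oracle(self, rng):
        checked = 0
        for k in range(30):
            patch = random_patch(rng)
            n_pix = int(patch.mask.sum())
            for angle in ANGLES:
                m = glrlm(patch, angle)
                mine = glrlm_features(m)
                runs = glrlm_bruteforce(patch.values.astype(int).tolist(),
                                        patch.mask.tolist(), angle)
                oracle = glrlm_features_bruteforce(runs, n_pix)
                for name, v in oracle.items():
                    assert mine[name] == pytest.approx(v, abs=1e-8), name
                checked += 1
        assert checked >= 100


class TestWavelet:
    def test_constant_patch_haar_identity(self):
        subs = dwt2_subbands(np.full((8, 8), 7.0))
        assert np.allclose(subs["LL"], 14.0)  # orthonormal Haar: LL = 2c
        for k in ("LH", "HL", "HH"):
            assert np.allclose(subs[k], 0.0)

    @pytest.mark.parametrize("shape", [(8, 8), (9, 7), (5, 12)])
    def test_subband_dims_are_ceil_half(self, shape, rng):
        vals = rng.random(shape)
        subs = dwt2_subbands(vals)
        expect = ((shape[0] + 1) // 2, (shape[1] + 1) // 2)
        for s in subs.values():
            assert s.shape == expect

    def test_parseval_energy_conservation(self, rng):
        for shape in ((8, 8), (11, 9), (16, 5)):
            vals = rng.random(shape) * 100
            subs = dwt2_subbands(vals)
            energy = sum(float((s ** 2).sum()) for s in subs.values())
            assert energy == pytest.approx(float((vals ** 2).sum()), rel=1e-6)

    def test_subband_mask_any_of_four_rule(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 3] = True  # source block (1, 1)
        patch = RoiPatch(values=np.arange(36, dtype=float).reshape(6, 6),
                         mask=mask | np.eye(6, dtype=bool), levels=16)
        subs = wavelet_subbands(patch)
        for s in subs.values():
            assert s.mask[1, 1]

    def test_too_small_patch_raises(self):
        from usradiomics.features import PatchTooSmallError

        patch = full_patch(np.ones((3, 3)), levels=8)
        with pytest.raises(PatchTooSmallError):
            wavelet_subbands(patch)


class TestExtractAll:
    def test_exactly_730_finite_values(self, rng):
        patch = random_patch(rng, max_side=12, levels=16)
        fv = extract_all(patch)
        assert len(fv) == 730
        assert np.isfinite(list(fv.values.values())).all()

    def test_deterministic(self, rng):
        vals = rng.integers(0, 16, size=(10, 10)).astype(float)
        p1 = full_patch(vals, levels=16)
        p2 = full_patch(vals.copy(), levels=16)
        v1 = list(extract_all(p1).values.values())
        v2 = list(extract_all(p2).values.values())
        assert v1 == v2  # bit-for-bit

    def test_rotation_angle_duality(self, rng):
        """Angle-0 co-occurrence of a patch equals angle-90 of its rotation."""
        for _ in range(5):
            vals = rng.integers(0, 8, size=(7, 9)).astype(float)
            f0 = glcm_features(glcm(full_patch(vals, levels=8), 0))
            f90 = glcm_features(glcm(full_patch(np.rot90(vals), levels=8), 90))
            for name in f0:
                assert f0[name] == pytest.approx(f90[name], abs=1e-10), name

    def test_translation_invariance(self, rng):
        from usradiomics.roi import RoiMask, extract_patch
        from test_roi import make_pair

        vals = rng.integers(0, 256, size=(9, 9)).astype(np.uint8)
        vectors = []
        for (r0, c0) in ((5, 5), (20, 31)):
            img = np.full((48, 48), 30, dtype=np.uint8)
            img[r0:r0 + 9, c0:c0 + 9] = vals
            m = np.zeros((48, 48), dtype=bool)
            m[r0:r0 + 9, c0:c0 + 9] = True
            patch = extract_patch(make_pair(img), RoiMask(mask=m))
            vectors.append(list(extract_all(patch).values.values()))
        assert vectors[0] == vectors[1]

    def test_intensity_shift_invariance(self, rng):
        """Min-max normalization removes any additive intensity offset."""
        from usradiomics.roi import quantize

        vals = rng.integers(10, 100, size=(8, 8)).astype(float)
        mask = np.ones((8, 8), dtype=bool)
        v1 = list(extract_all(quantize(vals, mask, 64)).values.values())
        v2 = list(extract_all(quantize(vals + 57.0, mask, 64)).values.values())
        assert v1 == v2

    def test_degenerate_channels_still_give_730(self):
        # 4x4 bounding box, constant: wavelet details vanish, GLCMs are
        # point masses — every feature must still be present and finite
        patch = full_patch(np.full((4, 4), 3.0), levels=8)
        fv = extract_all(patch)
        assert len(fv) == 730
        assert np.isfinite(list(fv.values.values())).all()
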
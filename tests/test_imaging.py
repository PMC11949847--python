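"""Center crop, color moments, co-occurrence matrix, and texture features."""

import numpy as np
import pytest

import gradefusion as gf
from gradefusion.imaging import (
    COLOR_FEATURE_NAMES,
    DEFAULT_OFFSETS,
    IMAGE_FEATURE_NAMES,
    TEXTURE_FEATURE_NAMES,
    quantize_gray,
)


def brute_force_glcm(gray, levels, offsets=DEFAULT_OFFSETS):
    """Direct double-loop realization of the co-occurrence definition."""
    h, w = gray.shape
    acc = np.zeros((levels, levels))
    for dr, dc in offsets:
        mat = np.zeros((levels, levels))
        for p in range(h):
            for q in range(w):
                if 0 <= p + dr < h and 0 <= q + dc < w:
                    mat[gray[p, q], gray[p + dr, q + dc]] += 1
        acc += mat + mat.T
    return acc / acc.sum()


def brute_force_haralick(p):
    """Naive-loop evaluation of all 16 texture descriptors (1-based levels)."""
    n = p.shape[0]
    out = {}
    log2 = lambda v: np.log2(v) if v > 0 else 0.0
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))
    p_sum = {k: 0.0 for k in range(2, 2 * n + 1)}
    p_diff = {k: 0.0 for k in range(n)}
    for i in range(n):
        for j in range(n):
            p_sum[i + j + 2] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    out["Entropy"] = -sum(p[i, j] * log2(p[i, j])
                          for i in range(n) for j in range(n))
    out["Energy"] = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    out["Inertia"] = sum((i - j) ** 2 * p[i, j]
                         for i in range(n) for j in range(n))
    out["Correlation"] = 0.0 if var < 1e-12 else sum(
        (i + 1 - mu) * (j + 1 - mu) * p[i, j]
        for i in range(n) for j in range(n)) / var
    out["Homogeneity"] = sum(p[i, j] / (1 + abs(i - j))
                             for i in range(n) for j in range(n))
    out["Dissimilarity"] = sum(abs(i - j) * p[i, j]
                               for i in range(n) for j in range(n))
    out["Sum_of_squares"] = sum((i + 1 - mu) ** 2 * p[i, j]
                                for i in range(n) for j in range(n))
    sa = sum(k * v for k, v in p_sum.items())
    out["Sum_average"] = sa
    out["Sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["Sum_entropy"] = -sum(v * log2(v) for v in p_sum.values())
    dm = sum(k * v for k, v in p_diff.items())
    out["Difference_variance"] = sum((k - dm) ** 2 * v
                                     for k, v in p_diff.items())
    out["Difference_entropy"] = -sum(v * log2(v) for v in p_diff.values())
    out["Cluster_shade"] = sum((i + j + 2 - 2 * mu) ** 3 * p[i, j]
                               for i in range(n) for j in range(n))
    out["Cluster_prominence"] = sum((i + j + 2 - 2 * mu) ** 4 * p[i, j]
                                    for i in range(n) for j in range(n))
    out["Inverse_difference_moment"] = sum(p[i, j] / (1 + (i - j) ** 2)
                                           for i in range(n) for j in range(n))
    out["Maximum_probability"] = max(p[i, j]
                                     for i in range(n) for j in range(n))
    return out


def _random_symmetric_glcm(rng, n=8):
    m = rng.random((n, n))
    m = m + m.T
    return gf.GLCMatrix(matrix=m / m.sum(), levels=n)


class TestCrop:
    def test_center_arithmetic_1200x1920(self):
        img = np.zeros((1200, 1920, 3))
        img[:, :, 0] = np.arange(1200)[:, None] / 2000.0
        img[:, :, 1] = np.arange(1920)[None, :] / 2000.0
        block = gf.crop_center_block(img, 400)
        rows = (block.pixels[:, 0, 0] * 2000).round().astype(int)
        cols = (block.pixels[0, :, 1] * 2000).round().astype(int)
        assert rows[0] == 400 and rows[-1] == 799
        assert cols[0] == 760 and cols[-1] == 1159

    def test_identity_crop(self):
        img = np.random.default_rng(0).random((400, 400, 3))
        assert np.array_equal(gf.crop_center_block(img, 400).pixels, img)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            gf.crop_center_block(np.zeros((399, 400, 3)), 400)


class TestColorStatistics:
    def test_constant_gray_block(self):
        stats = gf.color_statistics(gf.ImageBlock(np.full((50, 50, 3), 0.5)))
        for ch in ("R", "G", "B", "H", "S", "V", "L", "As", "Bs"):
            # L carries ~1e-15 accumulation noise from the Lab transform
            assert stats[f"{ch}_std"] == pytest.approx(0.0, abs=1e-9)
            assert stats[f"{ch}_skew"] == 0.0
            assert stats[f"{ch}_kurt"] == 0.0
        assert stats["S_ave"] == 0.0
        assert stats["V_ave"] == 0.5

    def test_pure_red_block(self):
        block = np.zeros((20, 20, 3))
        block[:, :, 0] = 1.0
        stats = gf.color_statistics(gf.ImageBlock(block))
        assert stats["H_ave"] == 0.0
        assert stats["S_ave"] == 1.0
        assert stats["V_ave"] == 1.0

    def test_two_point_kurtosis(self):
        """A half-0/half-1 channel has m4/m2² = 1."""
        block = np.zeros((20, 20, 3))
        block[:10, :, 0] = 1.0
        stats = gf.color_statistics(gf.ImageBlock(block))
        assert stats["R_kurt"] == pytest.approx(1.0)
        assert stats["R_skew"] == pytest.approx(0.0, abs=1e-12)

    def test_exactly_36_named_features(self):
        stats = gf.color_statistics(
            gf.ImageBlock(np.random.default_rng(1).random((16, 16, 3))))
        assert list(stats.index) == list(COLOR_FEATURE_NAMES)
        assert len(stats) == 36

    def test_moments_match_naive_accumulation(self, rng):
        """Channel moments agree with a per-pixel accumulation oracle."""
        block = gf.ImageBlock(rng.random((16, 16, 3)))
        stats = gf.color_statistics(block)
        x = block.pixels[:, :, 2].ravel()  # B channel, no conversion involved
        mean = sum(x) / x.size
        m2 = sum((v - mean) ** 2 for v in x) / x.size
        m3 = sum((v - mean) ** 3 for v in x) / x.size
        m4 = sum((v - mean) ** 4 for v in x) / x.size
        assert stats["B_ave"] == pytest.approx(mean, abs=1e-10)
        assert stats["B_std"] == pytest.approx(
            np.sqrt(m2 * x.size / (x.size - 1)), abs=1e-10)
        assert stats["B_skew"] == pytest.approx(m3 / m2 ** 1.5, abs=1e-10)
        assert stats["B_kurt"] == pytest.approx(m4 / m2 ** 2, abs=1e-10)


class TestGLCM:
    def test_two_by_two_hand_count(self):
        gray = np.array([[0, 0], [1, 1]])
        glcm = gf.compute_glcm(gray, levels=2, offsets=((0, 1),))
        np.testing.assert_allclose(glcm.matrix, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_block_single_cell(self):
        glcm = gf.compute_glcm(gf.ImageBlock(np.full((30, 30, 3), 0.4)))
        assert glcm.matrix.sum() == pytest.approx(1.0)
        assert np.count_nonzero(glcm.matrix) == 1
        assert glcm.matrix.max() == pytest.approx(1.0)

    def test_matches_brute_force_on_random_blocks(self, rng):
        for _ in range(10):
            block = gf.ImageBlock(rng.random((16, 16, 3)))
            glcm = gf.compute_glcm(block, levels=8)
            gray = quantize_gray(block.pixels, 8)
            np.testing.assert_array_equal(glcm.matrix,
                                          brute_force_glcm(gray, 8))

    def test_matches_skimage_direction_average(self, rng):
        """Cross-check against scikit-image's co-occurrence implementation."""
        from skimage.feature import graycomatrix

        gray = rng.integers(0, 8, size=(24, 24))
        ours = gf.compute_glcm(gray, levels=8).matrix
        sk = graycomatrix(gray.astype(np.uint8), distances=[1],
                          angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                          levels=8, symmetric=True)
        theirs = sk[:, :, 0, :].sum(axis=2).astype(float)
        np.testing.assert_allclose(ours, theirs / theirs.sum(), atol=1e-12)

    def test_normalized_and_symmetric(self, rng):
        block = gf.ImageBlock(rng.random((32, 32, 3)))
        glcm = gf.compute_glcm(block)
        assert abs(glcm.matrix.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(glcm.matrix, glcm.matrix.T, atol=1e-12)

    def test_levels_below_two_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            gf.compute_glcm(np.zeros((4, 4, 3)), levels=1)


class TestHaralick:
    def test_degenerate_single_cell(self):
        m = np.zeros((4, 4))
        m[2, 2] = 1.0
        tex = gf.haralick16(gf.GLCMatrix(matrix=m, levels=4))
        assert tex["Entropy"] == 0.0
        assert tex["Energy"] == 1.0
        assert tex["Inertia"] == 0.0
        assert tex["Homogeneity"] == 1.0
        assert tex["Maximum_probability"] == 1.0
        assert tex["Correlation"] == 0.0  # zero-variance convention

    def test_two_level_diagonal_matrix(self):
        m = np.array([[0.5, 0.0], [0.0, 0.5]])
        tex = gf.haralick16(gf.GLCMatrix(matrix=m, levels=2))
        assert tex["Entropy"] == pytest.approx(1.0)  # one bit
        assert tex["Energy"] == pytest.approx(0.5)
        assert tex["Inertia"] == 0.0
        assert tex["Correlation"] == pytest.approx(1.0)
        assert tex["Sum_average"] == pytest.approx(3.0)
        assert tex["Maximum_probability"] == pytest.approx(0.5)

    def test_matches_naive_loops(self, rng):
        for _ in range(5):
            glcm = _random_symmetric_glcm(rng)
            tex = gf.haralick16(glcm)
            oracle = brute_force_haralick(glcm.matrix)
            for name in TEXTURE_FEATURE_NAMES:
                assert tex[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            gf.haralick16(gf.GLCMatrix(matrix=np.ones((3, 3)), levels=3))

    def test_bounds(self, rng):
        glcm = gf.compute_glcm(gf.ImageBlock(rng.random((32, 32, 3))))
        tex = gf.haralick16(glcm)
        assert tex["Energy"] <= tex["Maximum_probability"] <= 1.0
        assert 0.0 <= tex["Entropy"] <= 2 * np.log2(glcm.levels)
        assert 0.0 < tex["Homogeneity"] <= 1.0

    def test_rotation_invariance(self, rng):
        """Direction averaging makes texture invariant to 90° rotation."""
        block = rng.random((40, 40, 3))
        a = gf.haralick16(gf.compute_glcm(gf.ImageBlock(block)))
        b = gf.haralick16(gf.compute_glcm(gf.ImageBlock(np.rot90(block).copy())))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)


class TestImageFeatureTable:
    def test_52_columns(self, image_table):
        assert image_table.n_features == 52
        assert image_table.feature_names == list(IMAGE_FEATURE_NAMES)
        assert image_table.provenance == "image"

    def test_empty_input(self):
        table = gf.image_feature_table([])
        assert table.n_samples == 0
        assert table.feature_names == list(IMAGE_FEATURE_NAMES)

    def test_permuting_inputs_permutes_rows_only(self, dataset):
        _, images, _ = dataset
        subset = images[:3]
        a = gf.image_feature_table(subset)
        b = gf.image_feature_table(subset[::-1])
        np.testing.assert_allclose(a.values.to_numpy(),
                                   b.values.to_numpy()[::-1], atol=0)
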
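import numpy as np
import pytest

from qdnntex.texture import (FEATURE_NAMES, TextureConfig, compute_glcm,
                             extract_features, glcm_contrast, glcm_correlation,
                             glcm_dissimilarity, glcm_energy, glcm_entropy,
                             glcm_features, glcm_homogeneity, offset_for_angle)

ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def glcm_bruteforce(img, d, theta, levels, symmetric):
    """Independent pair-counting oracle: explicit double loop."""
    dr, dc = offset_for_angle(d, theta)
    counts = np.zeros((levels, levels))
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[img[r, c], img[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


class TestComputeGLCM:
    def test_two_horizontal_pairs_by_hand(self):
        img = np.array([[0, 0], [1, 1]])
        g = compute_glcm(img, 1, 0.0, levels=2, symmetric=False)
        np.testing.assert_allclose(g.P, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_cell(self):
        g = compute_glcm(np.full((5, 5), 3), 1, 0.0, levels=8)
        expected = np.zeros((8, 8))
        expected[3, 3] = 1.0
        np.testing.assert_allclose(g.P, expected)

    @pytest.mark.parametrize("symmetric", [False, True])
    def test_matches_bruteforce_oracle(self, rng, symmetric):
        for _ in range(20):
            img = rng.integers(0, 8, size=(16, 16))
            for d in (1, 3):
                for theta in ANGLES:
                    got = compute_glcm(img, d, theta, 8, symmetric).P
                    want = glcm_bruteforce(img, d, theta, 8, symmetric)
                    np.testing.assert_array_equal(got, want)

    def test_normalized_and_nonnegative(self, rng):
        img = rng.integers(0, 16, size=(12, 12))
        for theta in ANGLES:
            g = compute_glcm(img, 2, theta, 16)
            assert g.P.min() >= 0
            assert g.P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_mode_is_symmetric(self, rng):
        img = rng.integers(0, 8, size=(10, 10))
        g = compute_glcm(img, 1, np.pi / 4, 8, symmetric=True)
        np.testing.assert_array_equal(g.P, g.P.T)

    def test_impossible_offset_raises(self):
        with pytest.raises(ValueError, match="no pixel pair"):
            compute_glcm(np.zeros((3, 3), dtype=int), 5, 0.0, 2)

    def test_agrees_with_skimage_symmetric(self, rng):
        """Cross-check against an established GLCM implementation.

        Conventions differ only by a possible vertical flip of the
        diagonal offsets, so theta=0 and pi/2 must match directly and
        the two diagonal matrices must match as an unordered pair.
        """
        skimage_feature = pytest.importorskip("skimage.feature")
        img = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        sk = skimage_feature.graycomatrix(
            img, distances=[1], angles=list(ANGLES), levels=8,
            symmetric=True, normed=True)
        ours = {theta: compute_glcm(img, 1, theta, 8, symmetric=True).P
                for theta in ANGLES}
        np.testing.assert_allclose(ours[0.0], sk[:, :, 0, 0], atol=1e-12)
        np.testing.assert_allclose(ours[np.pi / 2], sk[:, :, 0, 2], atol=1e-12)
        direct = (np.allclose(ours[np.pi / 4], sk[:, :, 0, 1]) and
                  np.allclose(ours[3 * np.pi / 4], sk[:, :, 0, 3]))
        flipped = (np.allclose(ours[np.pi / 4], sk[:, :, 0, 3]) and
                   np.allclose(ours[3 * np.pi / 4], sk[:, :, 0, 1]))
        assert direct or flipped


UNIFORM2 = np.full((2, 2), 0.25)
DIAG2 = np.array([[0.5, 0.0], [0.0, 0.5]])
SINGLE = np.array([[1.0, 0.0], [0.0, 0.0]])


class TestHaralickFeatures:
    @pytest.mark.parametrize("P,expected", [
        (UNIFORM2, 0.5), (SINGLE, 0.0)])
    def test_contrast(self, P, expected):
        assert glcm_contrast(P) == pytest.approx(expected, abs=1e-9)

    def test_contrast_checkerboard_is_one(self, checkerboard):
        g = compute_glcm(checkerboard.astype(int), 1, 0.0, 2, symmetric=True)
        assert glcm_contrast(g) == pytest.approx(1.0)

    @pytest.mark.parametrize("P,expected", [
        (UNIFORM2, 0.25), (SINGLE, 1.0), (DIAG2, 0.5)])
    def test_energy(self, P, expected):
        assert glcm_energy(P) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("P,expected", [
        (UNIFORM2, 0.0), (SINGLE, 0.0), (DIAG2, 1.0)])
    def test_correlation(self, P, expected):
        assert glcm_correlation(P) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("P,expected", [
        (UNIFORM2, 0.75), (DIAG2, 1.0),
        (np.array([[0.0, 1.0], [0.0, 0.0]]), 0.5)])
    def test_homogeneity(self, P, expected):
        assert glcm_homogeneity(P) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("P,expected", [
        (UNIFORM2, 2.0), (SINGLE, 0.0), (DIAG2, 1.0)])
    def test_entropy_bits(self, P, expected):
        assert glcm_entropy(P) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("P,expected", [
        (UNIFORM2, 0.5), (DIAG2, 0.0)])
    def test_dissimilarity(self, P, expected):
        assert glcm_dissimilarity(P) == pytest.approx(expected, abs=1e-9)

    def test_dissimilarity_far_corner(self):
        P = np.zeros((3, 3))
        P[0, 2] = 1.0
        assert glcm_dissimilarity(P) == pytest.approx(2.0)

    def test_correlation_invariant_under_transpose(self, rng):
        img = rng.integers(0, 8, size=(12, 12))
        g = compute_glcm(img, 1, 0.0, 8, symmetric=True)
        assert glcm_correlation(g.P) == pytest.approx(glcm_correlation(g.P.T))

    def test_contrast_dissimilarity_invariant_under_inversion(self, rng):
        img = rng.integers(0, 8, size=(12, 12))
        inv = 7 - img
        for theta in ANGLES:
            g = compute_glcm(img, 1, theta, 8, symmetric=True)
            gi = compute_glcm(inv, 1, theta, 8, symmetric=True)
            assert glcm_contrast(g) == pytest.approx(glcm_contrast(gi))
            assert glcm_dissimilarity(g) == pytest.approx(glcm_dissimilarity(gi))


class TestExtractFeatures:
    def test_default_grid_length_96(self, rng):
        vec = extract_features(rng.random((32, 32)))
        assert len(vec) == 96
        assert vec.names[0] == "d1_a0_contrast"
        assert len(vec.names) == len(set(vec.names))

    def test_constant_image_feature_extremes(self):
        vec = extract_features(np.full((32, 32), 0.5),
                               TextureConfig(distances=(1, 3), levels=8))
        for value, (d, ai, name) in zip(vec.values, vec.index):
            if name in ("contrast", "dissimilarity"):
                assert value == pytest.approx(0.0)
            elif name in ("energy", "homogeneity"):
                assert value == pytest.approx(1.0)

    def test_checkerboard_matches_manual_glcm(self, checkerboard):
        cfg = TextureConfig(distances=(1,), angles=(0.0,), levels=2)
        vec = extract_features(checkerboard, cfg)
        g = compute_glcm(checkerboard.astype(int), 1, 0.0, 2, symmetric=True)
        np.testing.assert_allclose(vec.values, glcm_features(g))

    def test_deterministic_ordering(self, rng):
        img = rng.random((24, 24))
        v1 = extract_features(img)
        v2 = extract_features(img)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert v1.index == v2.index

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            extract_features(np.random.default_rng(0).random((5, 5)))

    def test_window_mode_on_uniform_texture_matches_whole_image(self, checkerboard):
        whole = extract_features(checkerboard,
                                 TextureConfig(distances=(1,), angles=(0.0,), levels=2))
        windowed = extract_features(
            checkerboard, TextureConfig(distances=(1,), angles=(0.0,), levels=2,
                                        window=5, window_step=2))
        # a periodic texture has identical statistics in every window
        np.testing.assert_allclose(windowed.values, whole.values, atol=0.05)

    def test_energy_homogeneity_ranges(self, rng):
        vec = extract_features(rng.random((32, 32)), TextureConfig(levels=8))
        for value, (_, _, name) in zip(vec.values, vec.index):
            if name in ("energy", "homogeneity"):
                assert 0.0 < value <= 1.0
            if name == "entropy":
                assert value >= -1e-9
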
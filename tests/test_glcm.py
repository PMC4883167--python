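import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from eegtexture.glcm import GLCMatrix, compute_glcm, glcm_features
from eegtexture.errors import FeatureUndefinedError, ParameterError
from oracles import glcm_counts_brute, glcm_features_brute

ANGLES = (0, 45, 90, 135)


class TestCounts:
    def test_constant_image_horizontal(self):
        img = np.full((4, 5), 7, dtype=np.uint8)
        m = compute_glcm(img, delta=1, theta=0)
        assert m.counts[7, 7] == 16  # 4 rows x 4 horizontal pairs
        assert m.counts.sum() == 16

    def test_two_by_two_by_hand(self):
        m = compute_glcm(np.array([[0, 1], [1, 0]]), delta=1, theta=0, levels=2)
        expected = np.array([[0, 1], [1, 0]])
        assert np.array_equal(m.counts, expected)

    @pytest.mark.parametrize("theta", ANGLES)
    def test_matches_brute_force(self, theta, rng):
        for _ in range(25):
            img = rng.integers(0, 16, (16, 16))
            mine = compute_glcm(img, delta=1, theta=theta, levels=16).counts
            assert np.array_equal(mine, glcm_counts_brute(img, 1, theta, 16))

    def test_total_pairs_horizontal(self, rng):
        img = rng.integers(0, 256, (9, 13))
        m = compute_glcm(img, delta=1, theta=0)
        assert m.counts.sum() == 9 * (13 - 1)

    def test_transpose_swaps_0_and_90(self, rng):
        img = rng.integers(0, 8, (6, 9))
        a = compute_glcm(img.T, delta=1, theta=0, levels=8).counts
        b = compute_glcm(img, delta=1, theta=90, levels=8).counts
        # transposing the image turns horizontal pairs into vertical ones,
        # read in the opposite direction
        assert np.array_equal(a, b.T)

    def test_oversized_offset_warns_and_returns_zeros(self):
        img = np.zeros((2, 2), dtype=np.uint8)
        with pytest.warns(RuntimeWarning):
            m = compute_glcm(img, delta=5, theta=0)
        assert m.counts.sum() == 0


class TestFeatures:
    def test_constant_image_degenerate_conventions(self):
        m = compute_glcm(np.full((6, 6), 3, dtype=np.uint8), delta=1, theta=0)
        contrast, correlation, energy, homogeneity = glcm_features(m)
        assert contrast == 0.0
        assert correlation == 0.0  # zero marginal SD convention
        assert energy == 1.0
        assert homogeneity == 1.0

    def test_checkerboard_by_hand(self):
        """P = [[0, .5], [.5, 0]]: contrast 1, energy 0.5, homogeneity 0.5,
        correlation -1."""
        img = np.indices((8, 8)).sum(axis=0) % 2
        m = compute_glcm(img, delta=1, theta=0, levels=2)
        contrast, correlation, energy, homogeneity = glcm_features(m)
        assert contrast == pytest.approx(1.0)
        assert correlation == pytest.approx(-1.0)
        assert energy == pytest.approx(0.5)
        assert homogeneity == pytest.approx(0.5)

    @pytest.mark.parametrize("theta", ANGLES)
    def test_matches_brute_force(self, theta, rng):
        for _ in range(25):
            img = rng.integers(0, 16, (16, 16))
            m = compute_glcm(img, delta=1, theta=theta, levels=16)
            np.testing.assert_allclose(
                glcm_features(m), glcm_features_brute(m.counts), atol=1e-10
            )

    def test_matches_scikit_image(self, rng):
        """Independent library cross-check (theta=0, identical conventions;
        skimage 'energy' is sqrt of the angular second moment)."""
        from skimage.feature import graycomatrix, graycoprops

        img = rng.integers(0, 32, (16, 16)).astype(np.uint8)
        m = compute_glcm(img, delta=1, theta=0, levels=32)
        sk = graycomatrix(img, [1], [0], levels=32, symmetric=False)
        contrast, correlation, energy, _ = glcm_features(m)
        assert np.array_equal(m.counts, sk[:, :, 0, 0])
        assert contrast == pytest.approx(graycoprops(sk, "contrast")[0, 0], abs=1e-10)
        assert correlation == pytest.approx(graycoprops(sk, "correlation")[0, 0], abs=1e-10)
        assert energy == pytest.approx(graycoprops(sk, "ASM")[0, 0], abs=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(arrays(np.int64, (8, 8), elements=st.integers(0, 15)))
    def test_feature_ranges(self, img):
        m = compute_glcm(img, delta=1, theta=45, levels=16)
        contrast, correlation, energy, homogeneity = glcm_features(m)
        assert contrast >= 0
        assert 0 < energy <= 1
        assert 0 < homogeneity <= 1
        assert abs(correlation) <= 1 + 1e-9

    def test_all_zero_matrix_is_undefined(self):
        m = GLCMatrix(counts=np.zeros((4, 4), dtype=int), delta=1, theta=0, levels=4)
        with pytest.raises(FeatureUndefinedError):
            glcm_features(m)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"delta": 0},
        {"theta": 30},
    ],
)
def test_invalid_parameters(kwargs):
    with pytest.raises(ParameterError):
        compute_glcm(np.zeros((4, 4), dtype=np.uint8), **{"delta": 1, "theta": 0, **kwargs})
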
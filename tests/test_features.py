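import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planktodetect.candidates import Candidate
from planktodetect.features import (BoVWDictionary, BoVWVocabulary,
                                    bovw_histogram, build_dictionary,
                                    build_gabor_bank, colour_rows,
                                    extract_descriptor, gabor_sigma,
                                    texture_responses)
from planktodetect.io import BoundingBox, MicroscopyImage, PipelineConfig


def box_candidate(x0, y0, x1, y1):
    mask = np.ones((y1 - y0, x1 - x0), bool)
    return Candidate(0, np.empty((0, 2)), mask, BoundingBox(x0, y0, x1, y1),
                     ((y0 + y1) / 2, (x0 + x1) / 2), float(mask.sum()),
                     np.zeros(3))


class TestGaborSigma:
    def test_closed_form_value(self):
        # (1/(π·0.25))·√(ln2/2)·(2^1.5+1)/(2^1.5−1)
        expected = (1 / (math.pi * 0.25)) * math.sqrt(math.log(2) / 2) \
            * (2 ** 1.5 + 1) / (2 ** 1.5 - 1)
        assert abs(gabor_sigma(0.25, 1.5) - expected) < 1e-12
        assert gabor_sigma(0.25, 1.5) == pytest.approx(1.5695, abs=1e-3)

    def test_inverse_frequency_scaling(self):
        assert gabor_sigma(0.5, 1.5) == pytest.approx(gabor_sigma(0.25, 1.5) / 2)

    def test_unit_bandwidth_substitution(self):
        expected = 3 * math.sqrt(math.log(2) / 2) / (math.pi * 0.1)
        assert gabor_sigma(0.1, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gabor_sigma(0.0, 1.0)
        with pytest.raises(ValueError):
            gabor_sigma(0.25, -1.0)


class TestGaborBank:
    def test_orientation_set(self):
        bank = build_gabor_bank(0.25, 1.5, 4)
        np.testing.assert_allclose(bank.thetas,
                                   [0, math.pi / 4, math.pi / 2, 3 * math.pi / 4])
        assert len(bank.kernels) == 4
        side = bank.kernels[0].shape[0]
        assert side % 2 == 1 and side >= 2 * 3 * bank.sigma - 1

    def test_theta0_symmetries(self):
        """At θ=0 the real part is even and the imaginary part odd along x."""
        k = build_gabor_bank(0.25, 1.5, 4).kernels[0]
        np.testing.assert_allclose(k.real, k.real[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(k.imag, -k.imag[:, ::-1], atol=1e-12)

    def test_quarter_turn_rotation(self):
        """Kernels at θ and θ+π/2 are 90° rotations of each other.

        Rotating the sampled grid by a quarter turn reverses the carrier
        direction (θ−π/2 ≡ θ+π/2 mod π), which conjugates the complex kernel;
        the envelope and real part match exactly.
        """
        bank = build_gabor_bank(0.25, 1.5, 4)
        k0, k90 = bank.kernels[0], bank.kernels[2]
        np.testing.assert_allclose(np.rot90(k0), np.conj(k90), atol=1e-10)

    def test_matches_reference_kernel(self):
        """Cross-check against an independent Gabor construction."""
        from skimage.filters import gabor_kernel
        ours = build_gabor_bank(0.25, 1.5, 4)
        ref = gabor_kernel(0.25, theta=0.0, bandwidth=1.5)
        assert ours.kernels[0].shape == ref.shape
        # same envelope spread and carrier up to conjugation (sign of j)
        np.testing.assert_allclose(ours.kernels[0].real, ref.real, atol=1e-10)
        np.testing.assert_allclose(np.abs(ours.kernels[0].imag),
                                   np.abs(ref.imag), atol=1e-10)


class TestTextureResponses:
    def test_shape_and_ordering(self):
        img = MicroscopyImage(np.full((32, 40, 3), 128, np.uint8), 1.5)
        bank = build_gabor_bank(0.25, 1.5, 4)
        resp = texture_responses(img, bank)
        assert resp.shape == (32, 40, 8)

    def test_constant_image_imaginary_vanishes(self):
        img = MicroscopyImage(np.full((32, 32, 3), 200, np.uint8), 1.5)
        bank = build_gabor_bank(0.25, 1.5, 4)
        resp = texture_responses(img, bank)
        assert np.abs(resp[:, :, 1::2]).max() < 1e-8

    def test_sinusoid_maximises_matching_orientation(self):
        """A grating at (fc, θ=0) yields the largest response magnitude on the
        θ=0 filter of the bank."""
        fc = 0.25
        x = np.arange(64)
        grating = (128 + 100 * np.sin(2 * math.pi * fc * x))[None, :]
        pixels = np.repeat(grating, 64, axis=0)
        img = MicroscopyImage(np.stack([pixels] * 3, -1).astype(np.uint8), 1.5)
        bank = build_gabor_bank(fc, 1.5, 4)
        resp = texture_responses(img, bank)
        mags = [np.hypot(resp[20:44, 20:44, 2 * k],
                         resp[20:44, 20:44, 2 * k + 1]).mean()
                for k in range(4)]
        assert np.argmax(mags) == 0

    def test_whole_image_equals_per_crop_interior(self):
        """Interior responses agree whether computed whole-image or per crop."""
        rng = np.random.default_rng(3)
        pixels = rng.integers(0, 256, (48, 48, 3)).astype(np.uint8)
        img = MicroscopyImage(pixels, 1.5)
        bank = build_gabor_bank(0.25, 1.5, 4)
        whole = texture_responses(img, bank)
        crop = MicroscopyImage(pixels[8:40, 8:40], 1.5)
        cropped = texture_responses(crop, bank)
        r = bank.radius
        np.testing.assert_allclose(
            whole[8 + r:40 - r, 8 + r:40 - r],
            cropped[r:-r, r:-r], atol=1e-9)


class TestDictionary:
    def test_two_cloud_centroids(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0, 0.5, (50, 3))
        hi = rng.normal(20, 0.5, (50, 3))
        d = build_dictionary(np.vstack([lo, hi]), 2, seed=0)
        centres = sorted(d.centroids[:, 0].tolist())
        assert -2 < centres[0] < 2 and 18 < centres[1] < 22

    def test_determinism(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(0, 1, (100, 3))
        d1 = build_dictionary(rows, 5, seed=42)
        d2 = build_dictionary(rows, 5, seed=42)
        np.testing.assert_array_equal(d1.centroids, d2.centroids)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="smaller k"):
            build_dictionary(np.zeros((3, 3)), 5, seed=0)

    def test_degenerate_duplicates_rejected(self):
        rows = np.tile([1.0, 2.0, 3.0], (20, 1))
        with pytest.raises(ValueError, match="distinct"):
            build_dictionary(rows, 2, seed=0)

    def test_estimator_api(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(0, 1, (60, 3))
        voc = BoVWVocabulary(k=4, seed=1).fit(rows)
        H = voc.transform([rows[:10], rows[10:25]])
        assert H.shape == (2, 4)
        np.testing.assert_allclose(H.sum(axis=1), 1.0)
        assert voc.get_params()["k"] == 4


class TestHistogram:
    def test_worked_seven_row_example(self):
        d = BoVWDictionary("colour", np.array([[0.0], [10.0]]), 2)
        rows = np.array([[1.0], [1.0], [2.0], [8.0], [9.0], [9.0], [9.0]])
        np.testing.assert_allclose(bovw_histogram(rows, d), [3 / 7, 4 / 7])

    def test_one_hot(self):
        d = BoVWDictionary("colour", np.array([[0.0], [5.0], [10.0], [20.0]]), 4)
        rows = np.full((6, 1), 10.0)
        np.testing.assert_array_equal(bovw_histogram(rows, d), [0, 0, 1, 0])

    def test_tie_breaks_to_lowest_index(self):
        d = BoVWDictionary("colour", np.array([[0.0], [10.0]]), 2)
        np.testing.assert_array_equal(bovw_histogram(np.array([[5.0]]), d), [1, 0])

    def test_empty_region_rejected(self):
        d = BoVWDictionary("colour", np.array([[0.0], [10.0]]), 2)
        with pytest.raises(ValueError):
            bovw_histogram(np.empty((0, 1)), d)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sums_to_one_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        d = BoVWDictionary("colour", rng.normal(0, 5, (4, 3)), 4)
        rows = rng.normal(0, 5, (int(rng.integers(1, 40)), 3))
        h = bovw_histogram(rows, d)
        assert abs(h.sum() - 1.0) < 1e-9
        np.testing.assert_array_equal(
            h, bovw_histogram(rows[rng.permutation(len(rows))], d))


class TestExtractDescriptor:
    def make_image(self, fill=128):
        return MicroscopyImage(np.full((100, 100, 3), fill, np.uint8), 1.5)

    def test_growth_example(self):
        img = self.make_image()
        cand = box_candidate(10, 10, 30, 30)
        assert cand.bbox.grown(0.10, img.shape) == BoundingBox(8, 8, 32, 32)
        rows = colour_rows(img, cand, 0.10)
        assert rows.shape == (24 * 24, 3)

    def test_both_mode_concatenates(self):
        cfg = PipelineConfig()
        rng = np.random.default_rng(0)
        img = MicroscopyImage(rng.integers(0, 256, (60, 60, 3)).astype(np.uint8), 1.5)
        cand = box_candidate(20, 20, 40, 40)
        dc = BoVWDictionary("colour", rng.normal(128, 30, (5, 3)), 5)
        bank = build_gabor_bank(0.25, 1.5, 4)
        resp = texture_responses(img, bank)
        dt = BoVWDictionary("texture", rng.normal(0, 1, (5, 8)), 5)
        desc = extract_descriptor(img, cand, "both", {"colour": dc, "texture": dt},
                                  cfg, responses=resp)
        assert desc.shape == (10,)
        assert abs(desc.sum() - 1.0) < 1e-9

    def test_background_enters_descriptor(self):
        """Same foreground on different backgrounds gives different colour
        histograms — the implicit shape cue of the grown box."""
        cfg = PipelineConfig()
        rng = np.random.default_rng(1)
        dc = BoVWDictionary("colour", np.array([[40.0] * 3, [128.0] * 3,
                                                [230.0] * 3]), 3)
        for fill, expect_idx in ((128, 1), (230, 2)):
            img = self.make_image(fill)
            img.pixels[45:55, 45:55] = 40
            cand = box_candidate(45, 45, 55, 55)
            h = extract_descriptor(img, cand, "colour", {"colour": dc}, cfg)
            assert h[expect_idx] > 0
        img_a = self.make_image(128)
        img_a.pixels[45:55, 45:55] = 40
        img_b = self.make_image(230)
        img_b.pixels[45:55, 45:55] = 40
        cand = box_candidate(45, 45, 55, 55)
        ha = extract_descriptor(img_a, cand, "colour", {"colour": dc}, cfg)
        hb = extract_descriptor(img_b, cand, "colour", {"colour": dc}, cfg)
        assert not np.allclose(ha, hb)
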
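"""Preprocessing contracts: IDX I/O, downscaling, whitening, on/off
channels, and digit-pixel occlusion."""

import numpy as np
import pytest

from compcode.datatypes import ImageBatch
from compcode.idx import IdxFormatError, read_idx, write_idx
from compcode.preprocessing import (
    Preprocessor,
    Whitener,
    downscale,
    occlude,
    recombine_on_off,
    split_on_off,
    whitening_filter,
)


class TestIdx:
    def test_roundtrip(self, tmp_path, digits_small):
        ip, lp = tmp_path / "img.idx", tmp_path / "lab.idx"
        write_idx(digits_small, ip, lp)
        back = read_idx(ip, lp)
        assert back.pixels.shape == digits_small.pixels.shape
        assert np.array_equal(back.labels, digits_small.labels)
        # byte quantization error only; exact zeros survive
        assert np.abs(back.pixels - digits_small.pixels).max() <= 0.5 / 255
        assert np.array_equal(back.pixels == 0, digits_small.pixels == 0)

    def test_all_zero_images(self, tmp_path):
        batch = ImageBatch(np.zeros((2, 28, 28)), np.array([3, 7]))
        write_idx(batch, tmp_path / "i", tmp_path / "l")
        back = read_idx(tmp_path / "i", tmp_path / "l")
        assert back.pixels.shape == (2, 28, 28)
        assert not back.pixels.any()

    def test_bad_magic_rejected(self, tmp_path):
        batch = ImageBatch(np.zeros((2, 28, 28)))
        write_idx(batch, tmp_path / "i", tmp_path / "l")
        with pytest.raises(IdxFormatError, match="magic"):
            read_idx(tmp_path / "l", tmp_path / "i")  # swapped

    def test_count_mismatch_rejected(self, tmp_path):
        b1 = ImageBatch(np.zeros((2, 28, 28)))
        b2 = ImageBatch(np.zeros((3, 28, 28)))
        write_idx(b1, tmp_path / "i1", tmp_path / "l1")
        write_idx(b2, tmp_path / "i2", tmp_path / "l2")
        with pytest.raises(ValueError, match="mismatch"):
            read_idx(tmp_path / "i1", tmp_path / "l2")


class TestDownscale:
    def test_shape_28_to_12(self, digits_small):
        out = downscale(digits_small, 0.40)
        assert out.pixels.shape == (len(digits_small), 12, 12)

    def test_constant_image_preserved(self):
        batch = ImageBatch(np.full((1, 28, 28), 0.5))
        out = downscale(batch)
        assert np.allclose(out.pixels, 0.5, atol=1e-6)

    @staticmethod
    def _reference_bicubic(img, out_side):
        """Independent oracle: separable antialiased bicubic (Keys
        kernel a = -0.5, support widened by 1/scale, weights
        renormalized — the classic imresize definition)."""

        def keys(x):
            x = np.abs(x)
            return np.where(
                x <= 1,
                1.5 * x**3 - 2.5 * x**2 + 1,
                np.where(x <= 2, -0.5 * x**3 + 2.5 * x**2 - 4 * x + 2, 0.0),
            )

        n = img.shape[0]
        scale = out_side / n
        weights = np.zeros((out_side, n))
        for i in range(out_side):
            u = (i + 0.5) / scale - 0.5
            j = np.arange(n)
            weights[i] = keys((u - j) * scale)
            weights[i] /= weights[i].sum()
        return weights @ img @ weights.T

    def test_mass_against_reference_bicubic(self):
        """A central white block keeps its (area-scaled) mass and stays
        centered, matching an independent bicubic implementation."""
        img = np.zeros((28, 28))
        img[12:16, 12:16] = 1.0
        ours = downscale(ImageBatch(img[None])).pixels[0]
        ref = self._reference_bicubic(img, 12)
        scale = (12 / 28) ** 2
        assert abs(ours.sum() - img.sum() * scale) < 0.1 * img.sum() * scale
        assert np.abs(ours - np.clip(ref, 0, 1)).max() < 0.03
        cy, cx = np.unravel_index(np.argmax(ours), ours.shape)
        assert 4 <= cy <= 7 and 4 <= cx <= 7

    def test_background_stays_exact_zero(self, digits_small):
        out = downscale(digits_small)
        # zero must remain a meaningful background value
        assert (out.pixels == 0).mean() > 0.3

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            ImageBatch(np.zeros((1, 28, 27)))


class TestWhitening:
    def test_zero_in_zero_out(self, preprocessed):
        pp, _ = preprocessed
        assert not pp.whitener.transform(np.zeros((12, 12))).any()

    def test_dc_killed(self, preprocessed):
        pp, _ = preprocessed
        out = pp.whitener.transform(np.full((12, 12), 0.7))
        assert np.abs(out).max() < 1e-10

    def test_linearity(self, preprocessed, rng):
        pp, _ = preprocessed
        a, b = rng.standard_normal((2, 12, 12))
        lhs = pp.whitener.transform(2.0 * a + 3.0 * b)
        rhs = 2.0 * pp.whitener.transform(a) + 3.0 * pp.whitener.transform(b)
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_unit_mean_square_on_training_set(self, digits_small):
        small = downscale(digits_small)
        w = Whitener().fit(small)
        out = w.transform(small.pixels)
        assert abs(np.mean(out**2) - 1.0) < 1e-12

    def test_noise_spectrum_matches_filter(self, rng):
        """Whitened white noise has amplitude spectrum proportional to
        the analytic R(f) curve."""
        side = 12
        w = Whitener()
        noise = rng.standard_normal((4000, side, side))
        filt = whitening_filter(side)
        w.scale_ = 1.0
        out = w.transform(noise)
        amp = np.abs(np.fft.fft2(out, axes=(-2, -1))).mean(axis=0)
        mask = filt > 1e-12
        ratio = amp[mask] / filt[mask]
        assert ratio.std() / ratio.mean() < 0.05
        assert amp[0, 0] < 1e-10  # DC


class TestOnOffSplit:
    def test_dimension_288(self, preprocessed):
        _, X = preprocessed
        assert X.shape[1] == 288
        assert (X >= 0).all()

    def test_channels_disjoint(self, preprocessed):
        _, X = preprocessed
        assert np.abs(X[:, :144] * X[:, 144:]).max() == 0.0

    def test_lossless_recombination(self, rng):
        w = rng.standard_normal((5, 12, 12))
        assert np.array_equal(recombine_on_off(split_on_off(w)), w)

    def test_all_positive_input(self):
        w = np.abs(np.random.default_rng(0).standard_normal((12, 12)))
        x = split_on_off(w)
        assert not x[144:].any()


class TestOcclusion:
    def test_level_zero_identity(self, digits_small):
        out = occlude(digits_small, 0.0, seed=9)
        assert np.array_equal(out.pixels, digits_small.pixels)

    def test_exact_count(self):
        img = np.zeros((1, 8, 8))
        img[0, 2, :5] = 0.5
        img[0, 3, :5] = 0.5  # 10 non-zero pixels
        out = occlude(ImageBatch(img), 0.5, seed=1)
        assert (out.pixels > 0).sum() == 5

    def test_rounding_half_away_from_zero(self):
        img = np.zeros((1, 8, 8))
        img[0, 0, :5] = 1.0  # 5 nonzero; 0.5*5 = 2.5 -> 3 removed
        out = occlude(ImageBatch(img), 0.5, seed=1)
        assert (out.pixels > 0).sum() == 2

    def test_background_untouched_and_nested_zeros(self, digits_small):
        out = occlude(digits_small, 0.3, seed=4)
        was_zero = digits_small.pixels == 0
        assert (out.pixels[was_zero] == 0).all()
        # zero set of input is a subset of zero set of output
        assert ((out.pixels == 0) | ~was_zero).all()

    def test_level_one_erases_digit(self, digits_small):
        out = occlude(digits_small, 1.0, seed=2)
        assert not out.pixels.any()

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_bad_level_rejected(self, digits_small, bad):
        with pytest.raises(ValueError):
            occlude(digits_small, bad, seed=0)

    def test_monotone_in_level(self, digits_small):
        counts = [
            (occlude(digits_small, lv, seed=5).pixels > 0).sum()
            for lv in (0.0, 0.2, 0.4, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_order_independent_substreams(self, digits_small):
        """Occluding a subset gives the same pixels as occluding the
        full batch, because streams are keyed by (seed, index)."""
        full = occlude(digits_small, 0.4, seed=11)
        sub = occlude(digits_small.subset(np.arange(10)), 0.4, seed=11)
        assert np.array_equal(full.pixels[:10], sub.pixels)


def test_preprocessor_occlusion_level_zero_matches_plain(digits_small):
    pp = Preprocessor().fit(digits_small)
    a = pp.transform(digits_small)
    b = pp.transform(digits_small, occlusion_level=0.0, occlusion_seed=3)
    assert np.array_equal(a, b)
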
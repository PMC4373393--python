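"""Image preprocessing: downscaling, whitening, on/off channels, occlusion.

The pipeline mimics the early visual system up to the LGN: digit images
are downscaled to 12 x 12, spectrally whitened with a low-pass-windowed
ramp filter, and split into non-negative on-center / off-center channels,
giving a 288-dimensional input vector per image.  Occlusion deletes a
fixed fraction of a digit's non-zero pixels before any of this happens.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from compcode.datatypes import ImageBatch

#: pixels this close to zero after interpolation are treated as background
BACKGROUND_SNAP = 1e-3


def downscale(batch: ImageBatch, factor: float = 0.40) -> ImageBatch:
    """Bicubic antialiased downscale (28 x 28 -> 12 x 12 at factor 0.40).

    The output side length is ``ceil(factor * side)``.  Resampling uses
    a support-scaled cubic kernel on float images (antialiasing by
    kernel widening, the behaviour of the usual image-resize tools), so
    total image mass is conserved to about a percent.  Values are
    clipped to [0, 1] and near-zero interpolation residue (< 1e-3) is
    snapped back to exactly 0 so the digit/background distinction that
    occlusion relies on survives resizing.
    """
    side = batch.image_size
    out_side = int(np.ceil(factor * side))
    out = np.empty((len(batch), out_side, out_side))
    for i, img in enumerate(batch.pixels):
        resized = Image.fromarray(img.astype(np.float32), mode="F").resize(
            (out_side, out_side), Image.Resampling.BICUBIC
        )
        out[i] = np.asarray(resized, dtype=np.float64)
    out = np.clip(out, 0.0, 1.0)
    out[out < BACKGROUND_SNAP] = 0.0
    return ImageBatch(out, batch.labels.copy())


def whitening_filter(side: int, f0_ratio: float = 0.78) -> np.ndarray:
    """Frequency response R(f) = f * exp(-(f/f0)^4) on the FFT grid.

    ``f`` is radial spatial frequency in cycles/image; ``f0`` is the
    low-pass cutoff as a fraction of the Nyquist frequency (side/2).
    The ramp removes pairwise pixel correlations of natural-image-like
    1/f spectra; the quartic window suppresses the noisiest high
    frequencies.  DC gain is exactly 0, so whitened images are zero-mean.
    """
    freqs = np.fft.fftfreq(side) * side  # cycles per image
    fx, fy = np.meshgrid(freqs, freqs, indexing="ij")
    f = np.hypot(fx, fy)
    f0 = f0_ratio * (side / 2.0)
    return f * np.exp(-((f / f0) ** 4))


class Whitener:
    """Olshausen-and-Field-style frequency-domain whitening.

    The filter itself is fixed by the image size; the only fitted
    quantity is a global output scale, chosen once on the training set
    so whitened training images have unit mean-square value, and then
    frozen for test-time use.
    """

    def __init__(self, f0_ratio: float = 0.78):
        self.f0_ratio = f0_ratio
        self.scale_: float | None = None
        self._filter: np.ndarray | None = None

    def _apply_filter(self, images: np.ndarray) -> np.ndarray:
        side = images.shape[-1]
        if self._filter is None or self._filter.shape[0] != side:
            self._filter = whitening_filter(side, self.f0_ratio)
        spectra = np.fft.fft2(images, axes=(-2, -1))
        return np.real(np.fft.ifft2(spectra * self._filter, axes=(-2, -1)))

    def fit(self, batch: ImageBatch) -> "Whitener":
        filtered = self._apply_filter(batch.pixels)
        ms = np.mean(filtered**2)
        if ms <= 0:
            raise ValueError("cannot normalize whitening scale on all-zero data")
        self.scale_ = 1.0 / np.sqrt(ms)
        return self

    def transform(self, images: np.ndarray) -> np.ndarray:
        """Whiten a (n, h, w) stack or a single (h, w) image."""
        if self.scale_ is None:
            raise RuntimeError("Whitener is not fitted")
        single = images.ndim == 2
        out = self._apply_filter(images[None] if single else images) * self.scale_
        return out[0] if single else out

    def fit_transform(self, batch: ImageBatch) -> np.ndarray:
        return self.fit(batch).transform(batch.pixels)


def split_on_off(whitened: np.ndarray) -> np.ndarray:
    """Split signed whitened images into on/off channel vectors.

    The positive part and the absolute value of the negative part are
    flattened and concatenated: a 12 x 12 image becomes a 288-vector
    whose first 144 entries are the on channel and last 144 the off
    channel.  The split is lossless: ``x[:144] - x[144:]`` reshaped
    recovers the whitened image exactly, and no pixel is active in both
    channels.
    """
    single = whitened.ndim == 2
    w = whitened[None] if single else whitened
    n = w.shape[0]
    flat = w.reshape(n, -1)
    x = np.concatenate([np.maximum(flat, 0.0), np.maximum(-flat, 0.0)], axis=1)
    return x[0] if single else x


def recombine_on_off(x: np.ndarray, side: int | None = None) -> np.ndarray:
    """Inverse of :func:`split_on_off`: on minus off, reshaped square."""
    single = x.ndim == 1
    xv = x[None] if single else x
    half = xv.shape[1] // 2
    if side is None:
        side = int(round(np.sqrt(half)))
    img = (xv[:, :half] - xv[:, half:]).reshape(-1, side, side)
    return img[0] if single else img


def occlude(batch: ImageBatch, level: float, seed: int) -> ImageBatch:
    """Randomly delete a fraction ``level`` of each digit's non-zero pixels.

    For each image independently, exactly ``round(level * n_nonzero)``
    non-zero pixels (round half away from zero) are chosen uniformly
    without replacement and set to 0.  Background pixels are never
    touched.  Each image uses an RNG substream keyed by ``(seed, image
    index)``, so the result is reproducible and independent of
    processing order.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"occlusion level must be in [0, 1], got {level}")
    out = batch.pixels.copy()
    if level > 0.0:
        for i in range(len(out)):
            img = out[i]
            nz_flat = np.flatnonzero(img)
            k = int(np.floor(level * nz_flat.size + 0.5))
            if k == 0:
                continue
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            kill = rng.choice(nz_flat, size=k, replace=False)
            img.reshape(-1)[kill] = 0.0
    return ImageBatch(out, batch.labels.copy())


class Preprocessor:
    """Downscale + whiten + on/off split, with the whitening scale frozen
    on the training set.

    Parameters
    ----------
    resize_factor : float
        Downscaling factor (0.40 maps 28 x 28 to 12 x 12).
    f0_ratio : float
        Whitening cutoff as a fraction of Nyquist.
    """

    def __init__(self, resize_factor: float = 0.40, f0_ratio: float = 0.78):
        self.resize_factor = resize_factor
        self.whitener = Whitener(f0_ratio)
        self.side_: int | None = None

    def fit(self, train_batch: ImageBatch) -> "Preprocessor":
        small = downscale(train_batch, self.resize_factor)
        self.side_ = small.image_size
        self.whitener.fit(small)
        return self

    def transform(
        self,
        batch: ImageBatch,
        occlusion_level: float = 0.0,
        occlusion_seed: int = 0,
    ) -> np.ndarray:
        """Raw images -> (n, 2 * side^2) on/off input vectors.

        Occlusion, if requested, deletes non-zero pixels of the
        *downscaled* image — the last point in the pipeline where the
        digit/background distinction exists — immediately before
        whitening, so the deleted information cannot be re-interpolated
        by the resize step.
        """
        small = downscale(batch, self.resize_factor)
        if occlusion_level > 0.0:
            small = occlude(small, occlusion_level, occlusion_seed)
        return split_on_off(self.whitener.transform(small.pixels))

    def fit_transform(self, train_batch: ImageBatch) -> np.ndarray:
        return self.fit(train_batch).transform(train_batch)

    @property
    def n_inputs(self) -> int:
        if self.side_ is None:
            raise RuntimeError("Preprocessor is not fitted")
        return 2 * self.side_ * self.side_
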
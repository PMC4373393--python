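"""Core containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageBatch:
    """A stack of square grayscale images with class labels.

    Attributes
    ----------
    pixels : ndarray, shape (n_images, h, w)
        Intensities in [0, 1].  Background is exactly 0 — occlusion and
        the synthetic generator both rely on the zero/non-zero pixel
        distinction being well defined.
    labels : ndarray, shape (n_images,)
        Integer class ids in {0..9}.
    """

    pixels: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be 3-D, got shape {self.pixels.shape}")
        if self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValueError("images must be square")
        if self.labels is None:
            self.labels = np.zeros(len(self.pixels), dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.pixels):
            raise ValueError(
                f"{len(self.pixels)} images but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def image_size(self) -> int:
        return self.pixels.shape[1]

    def subset(self, idx: np.ndarray) -> "ImageBatch":
        return ImageBatch(self.pixels[idx].copy(), self.labels[idx].copy())

    def copy(self) -> "ImageBatch":
        return ImageBatch(self.pixels.copy(), self.labels.copy())
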
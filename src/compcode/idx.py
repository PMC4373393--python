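"""Reading and writing the IDX binary format used by MNIST.

IDX is big-endian: a 4-byte magic number (two zero bytes, a dtype code,
the number of dimensions), one 4-byte big-endian int per dimension, then
the raw data.  MNIST image files carry magic 2051 (unsigned byte, 3-D)
and label files magic 2049 (unsigned byte, 1-D).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from compcode.datatypes import ImageBatch

IMAGES_MAGIC = 2051
LABELS_MAGIC = 2049


class IdxFormatError(ValueError):
    """Raised for a bad magic number or malformed IDX header."""


def _read_header(fh, expected_magic: int, path) -> tuple[int, ...]:
    magic_bytes = fh.read(4)
    if len(magic_bytes) < 4:
        raise IdxFormatError(f"{path}: truncated IDX header")
    (magic,) = struct.unpack(">i", magic_bytes)
    if magic != expected_magic:
        raise IdxFormatError(
            f"{path}: bad magic number {magic}, expected {expected_magic}"
        )
    ndim = magic & 0xFF
    dims = struct.unpack(f">{ndim}i", fh.read(4 * ndim))
    return dims


def read_idx(images_path, labels_path) -> ImageBatch:
    """Load an MNIST-style image/label file pair.

    Pixel values are rescaled from {0..255} to [0, 1].  Raises
    :class:`IdxFormatError` on a wrong magic number and ``ValueError``
    if the two files disagree on the number of items.
    """
    images_path, labels_path = Path(images_path), Path(labels_path)
    with open(images_path, "rb") as fh:
        n, h, w = _read_header(fh, IMAGES_MAGIC, images_path)
        data = np.frombuffer(fh.read(n * h * w), dtype=np.uint8)
    if data.size != n * h * w:
        raise IdxFormatError(f"{images_path}: truncated pixel data")
    pixels = data.reshape(n, h, w).astype(np.float64) / 255.0

    with open(labels_path, "rb") as fh:
        (n_labels,) = _read_header(fh, LABELS_MAGIC, labels_path)
        labels = np.frombuffer(fh.read(n_labels), dtype=np.uint8)
    if labels.size != n_labels:
        raise IdxFormatError(f"{labels_path}: truncated label data")
    if n_labels != n:
        raise ValueError(
            f"image/label count mismatch: {n} images vs {n_labels} labels"
        )
    return ImageBatch(pixels, labels.astype(np.int64))


def write_idx(batch: ImageBatch, images_path, labels_path) -> None:
    """Write a batch as an MNIST-compatible IDX file pair.

    Intensities are quantized to unsigned bytes, so round-tripping
    loses sub-1/255 precision; exact zeros stay exactly zero.
    """
    n, h, w = batch.pixels.shape
    px = np.clip(np.rint(batch.pixels * 255.0), 0, 255).astype(np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", IMAGES_MAGIC, n, h, w))
        fh.write(px.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", LABELS_MAGIC, n))
        fh.write(batch.labels.astype(np.uint8).tobytes())
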
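"""Synthetic MNIST-like digit generator.

Each digit class 0-9 is defined by a fixed polyline skeleton in a unit
box.  A sample is rendered at 28 x 28 by jittering the skeleton (small
rotation, translation and stroke-width variation), painting a Gaussian
intensity profile around the strokes, and hard-thresholding the tails so
the background is exactly 0 — matching MNIST's centered, size-normalized
digits on a black (zero) background closely enough to exercise every
downstream stage (occlusion semantics included) without any download.
Visual realism is a non-goal.
"""

from __future__ import annotations

import numpy as np

from compcode.datatypes import ImageBatch

IMAGE_SIDE = 28
#: intensity below this (relative to stroke peak) is background -> exact 0
_PROFILE_CUTOFF = 0.08


def _arc(cx, cy, rx, ry, deg0, deg1, n=14):
    """Polyline approximating an elliptic arc; y grows downward, positive
    angles point up."""
    th = np.radians(np.linspace(deg0, deg1, n))
    return np.column_stack([cx + rx * np.cos(th), cy - ry * np.sin(th)])


def _pts(*xy):
    return np.asarray(xy, dtype=float)


def _skeletons() -> dict[int, list[np.ndarray]]:
    """Stroke polylines per class, in a [0,1]^2 box (y down)."""
    return {
        0: [_arc(0.5, 0.5, 0.30, 0.42, 90, 450, 20)],
        1: [_pts((0.38, 0.22), (0.56, 0.05), (0.56, 0.95))],
        2: [
            np.vstack(
                [
                    _arc(0.5, 0.30, 0.30, 0.25, 160, -20, 12),
                    _pts((0.18, 0.93), (0.82, 0.93)),
                ]
            )
        ],
        3: [
            _arc(0.5, 0.28, 0.26, 0.23, 150, -80, 12),
            _arc(0.5, 0.72, 0.28, 0.24, 80, -150, 12),
        ],
        4: [
            _pts((0.62, 0.05), (0.18, 0.60), (0.85, 0.60)),
            _pts((0.62, 0.30), (0.62, 0.95)),
        ],
        5: [
            np.vstack(
                [
                    _pts((0.78, 0.08), (0.25, 0.08), (0.22, 0.45)),
                    _arc(0.47, 0.66, 0.28, 0.25, 100, -120, 12),
                ]
            )
        ],
        6: [
            _arc(0.55, 0.48, 0.36, 0.42, 80, 262, 14),
            _arc(0.50, 0.70, 0.22, 0.20, -90, 270, 16),
        ],
        7: [_pts((0.18, 0.08), (0.82, 0.08), (0.42, 0.95))],
        8: [
            _arc(0.5, 0.28, 0.22, 0.21, 90, 450, 16),
            _arc(0.5, 0.73, 0.26, 0.22, 90, 450, 16),
        ],
        9: [
            _arc(0.5, 0.32, 0.24, 0.25, 90, 450, 16),
            _pts((0.74, 0.34), (0.68, 0.95)),
        ],
    }


_SKELETONS = _skeletons()


def _segment_distances(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min distance from each point (m, 2) to the polyline's segments."""
    a = polyline[:-1]  # (s, 2)
    b = polyline[1:]
    ab = b - a
    denom = np.einsum("sd,sd->s", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]  # (m, s, 2)
    t = np.clip(np.einsum("msd,sd->ms", ap, ab) / denom, 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def render_glyph(
    class_id: int,
    rng: np.random.Generator,
    stroke_width: float = 1.7,
    max_rotation_deg: float = 15.0,
    max_translation_px: float = 2.0,
) -> np.ndarray:
    """Render one jittered digit at 28 x 28 with exact-zero background."""
    angle = np.radians(rng.uniform(-max_rotation_deg, max_rotation_deg))
    shift = rng.uniform(-max_translation_px, max_translation_px, size=2)
    width = stroke_width * rng.uniform(0.8, 1.25)
    peak = rng.uniform(0.7, 1.0)
    scale = rng.uniform(0.92, 1.05)

    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    # unit box -> centered 19 px box inside the 28 px frame, then jitter
    box = 19.0 * scale
    origin = (IMAGE_SIDE - 1) / 2.0

    ys, xs = np.mgrid[0:IMAGE_SIDE, 0:IMAGE_SIDE]
    points = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)

    img = np.zeros(IMAGE_SIDE * IMAGE_SIDE)
    sigma = width / 2.0
    for poly in _SKELETONS[class_id]:
        p = (poly - 0.5) @ rot.T * box
        p += origin + shift
        d = _segment_distances(points, p)
        img = np.maximum(img, np.exp(-(d**2) / (2.0 * sigma**2)))
    img = peak * img
    img[img < peak * _PROFILE_CUTOFF] = 0.0
    return img.reshape(IMAGE_SIDE, IMAGE_SIDE)


def generate_digits(n: int, seed: int, **glyph_kwargs) -> ImageBatch:
    """Generate ``n`` labeled digits, classes drawn uniformly over 0-9.

    Deterministic given ``seed``: each image is rendered from an RNG
    substream keyed by ``(seed, sample index)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    label_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD161]))
    labels = label_rng.integers(0, 10, size=n)
    pixels = np.empty((n, IMAGE_SIDE, IMAGE_SIDE))
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        pixels[i] = render_glyph(int(labels[i]), rng, **glyph_kwargs)
    return ImageBatch(pixels, labels)
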
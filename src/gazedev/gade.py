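"""Gaze-deviation (GaDe) images.

A GaDe image summarizes one subject's whole session as an S x S RGB image.
For each retained gaze pair the three fixation deviations are computed —
left eye to target (d_l), right eye to target (d_r), and the binocular
midpoint to target (d_c) — and each deviation is painted at its gaze
point's screen position into one channel (R = left, G = right, B = center)
after per-channel normalization to 0..255:

    v = round(d / max_d * 255)

where ``max_d`` is that channel's maximum deviation over *all* pairs of the
session and rounding is half-away-from-zero.  Pixels never hit by a gaze
point stay 0, so large deviations dominate the picture: a well-fixating
subject yields a few dim clusters at the nine targets, a strabismic subject
a second constellation of bright points displaced by the deviation angle.

Off-screen gaze points (coordinates outside [0, 1]) are clipped to the image
border rather than dropped — an extreme deviation is exactly the diagnostic
signal, so it must stay visible.  When several points land on the same pixel
the maximum intensity wins, which keeps rasterization order-independent and
preserves the worst deviation at that location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .core import GazeSession, euclidean_deviation

__all__ = [
    "DeviationRecord",
    "GaDeImage",
    "compute_deviations",
    "intensity",
    "rasterize",
    "brighten_for_display",
]


@dataclass(frozen=True)
class DeviationRecord:
    """Fixation deviations of one gaze pair against its target."""

    target_index: int
    left: tuple[float, float]
    right: tuple[float, float]
    center: tuple[float, float]
    d_left: float
    d_right: float
    d_center: float


@dataclass(frozen=True)
class GaDeImage:
    """Three integer deviation maps at CNN input size, plus provenance.

    ``left``, ``right``, ``center`` are S x S integer arrays in [0, 255];
    channel order in the exported RGB image is (R, G, B) = (left, right,
    center).  ``maxima`` stores the per-channel normalizing deviations.
    """

    left: np.ndarray
    right: np.ndarray
    center: np.ndarray
    size: int
    subject_id: str
    maxima: tuple[float, float, float]

    @property
    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.left, self.right, self.center)

    def as_array(self) -> np.ndarray:
        """(S, S, 3) uint8 RGB array."""
        return np.stack(self.channels, axis=-1).astype(np.uint8)

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.as_array(), mode="RGB")

    def save_png(self, path) -> None:
        self.to_pil().save(path, format="PNG")


def compute_deviations(session: GazeSession) -> list[DeviationRecord]:
    """One deviation record per retained gaze pair, in session order.

    The binocular center is the component-wise midpoint of the two gaze
    points; note d_c is *not* bounded by the per-eye deviations (two eyes on
    opposite sides of the target can cancel at the center, and a common
    offset survives it).
    """
    if not session.pairs:
        raise ValueError("session has no gaze pairs")
    records = []
    for p in session.pairs:
        target = session.protocol.target(p.target_index).position
        center = ((p.left[0] + p.right[0]) / 2.0, (p.left[1] + p.right[1]) / 2.0)
        records.append(
            DeviationRecord(
                target_index=p.target_index,
                left=p.left,
                right=p.right,
                center=center,
                d_left=euclidean_deviation(p.left, target),
                d_right=euclidean_deviation(p.right, target),
                d_center=euclidean_deviation(center, target),
            )
        )
    return records


def intensity(d: float, d_max: float) -> int:
    """Map a deviation to its 8-bit map value: round(d / d_max * 255).

    Rounding is half-away-from-zero (127.5 -> 128).  A channel whose maximum
    deviation is zero (perfect fixation throughout) stays all-zero.
    """
    if d < 0 or not math.isfinite(d):
        raise ValueError(f"deviation must be finite and >= 0, got {d}")
    if d_max == 0.0:
        return 0
    if d > d_max:
        raise ValueError(f"deviation {d} exceeds channel maximum {d_max}")
    return int(math.floor(d / d_max * 255.0 + 0.5))


def _to_pixel(coords: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Map normalized (x, y) to (row, col); off-screen points clip to border."""
    clipped = np.clip(coords, 0.0, np.nextafter(1.0, 0.0))
    cols = np.floor(clipped[:, 0] * size).astype(np.intp)
    rows = np.floor(clipped[:, 1] * size).astype(np.intp)
    return rows, cols


def rasterize(session: GazeSession, size: int = 224) -> GaDeImage:
    """Build the GaDe image of a session at ``size`` x ``size``.

    The standard sizes are 224 (VGG-style inputs) and 227 (AlexNet); any
    size >= 32 is accepted.  Per channel, deviations are normalized by the
    session-wide maximum of that channel, painted at the corresponding gaze
    (or center) position with floor(coord * S) pixel mapping, and pixel
    collisions keep the maximum intensity.
    """
    if size < 32:
        raise ValueError(f"image size must be >= 32, got {size}")
    records = compute_deviations(session)  # raises on empty session
    out = []
    maxima = []
    for points, dists in (
        ([r.left for r in records], [r.d_left for r in records]),
        ([r.right for r in records], [r.d_right for r in records]),
        ([r.center for r in records], [r.d_center for r in records]),
    ):
        d = np.asarray(dists, dtype=float)
        d_max = float(d.max())
        maxima.append(d_max)
        chan = np.zeros((size, size), dtype=np.int64)
        if d_max > 0.0:
            v = np.floor(d / d_max * 255.0 + 0.5).astype(np.int64)
            rows, cols = _to_pixel(np.asarray(points, dtype=float), size)
            np.maximum.at(chan, (rows, cols), v)
        out.append(chan)
    return GaDeImage(
        left=out[0],
        right=out[1],
        center=out[2],
        size=size,
        subject_id=session.subject_id,
        maxima=(maxima[0], maxima[1], maxima[2]),
    )


def brighten_for_display(img: GaDeImage, offset: int = 50) -> np.ndarray:
    """Visualization aid only: lift nonzero (gaze-hit) pixels by ``offset``.

    Background zeros are untouched and values saturate at 255.  Never part
    of the classification path — features are always extracted from the raw
    maps.
    """
    if not 0 <= offset <= 255:
        raise ValueError(f"offset must be in [0, 255], got {offset}")
    arr = img.as_array().astype(np.int64)
    lifted = np.where(arr > 0, np.minimum(arr + offset, 255), 0)
    return lifted.astype(np.uint8)
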
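"""Shape-from-focus: height maps and extended-depth-of-focus composites.

A z-stack is an ordered series of grayscale images of the same scene taken at
focal planes spaced ``z_step_um`` apart, with slice 0 the lowest plane (the
slide surface) and index increasing upward. For every pixel, the slice on
which the local image is sharpest tells us the height of the surface at that
pixel. Sharpness is measured as the local intensity variance in a square
kernel window (the classic shape-from-focus focus operator); the per-pixel
argmax over slices is stored as an 8-bit *height map*, scaled so that slice 0
maps to grey value 0 and the top slice to 255.

The encoding and its inverse are fixed as an exact round-trip pair:

    encode: H = round(255 * b / (s - 1))          (b = best slice index)
    decode: height = round(H * (s - 1) / 255) * Z  (µm above the slide)

with round-half-away-from-zero throughout. ``decode(encode(b)) == b * Z``
exactly for every slice index b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import boxcar_count, boxcar_sum, round_half_away

__all__ = [
    "ZStack",
    "HeightMap",
    "focus_measure",
    "build_height_map",
    "build_edf",
    "encode_slice",
    "decode_height",
]


@dataclass
class ZStack:
    """Ordered grayscale slices with acquisition geometry.

    slices
        Array of shape ``(s, H, W)``; index 0 is the lowest focal plane.
    z_step_um
        Vertical distance between consecutive focal planes (µm).
    px_um
        Lateral pixel size (µm per pixel).
    """

    slices: np.ndarray
    z_step_um: float
    px_um: float

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (s, H, W) array")
        if self.s < 2:
            raise ValueError("a z-stack needs at least 2 slices")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.px_um <= 0:
            raise ValueError("px_um must be positive")

    @property
    def s(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple:
        return self.slices.shape[1:]


@dataclass
class HeightMap:
    """8-bit encoded per-pixel best-focus slice index plus geometry."""

    encoded: np.ndarray  # integer grid, values 0-255
    valid: np.ndarray  # boolean mask, same dims
    s: int
    z_step_um: float
    px_um: float

    def __post_init__(self):
        self.encoded = np.asarray(self.encoded)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.encoded.shape != self.valid.shape:
            raise ValueError("encoded and valid must have the same shape")
        e = self.encoded[self.valid]
        if e.size and (e.min() < 0 or e.max() > 255):
            raise ValueError("encoded values must lie in [0, 255]")


def focus_measure(image: np.ndarray, kernel: int = 11) -> np.ndarray:
    """Per-pixel local intensity variance in a ``kernel`` x ``kernel`` window.

    Windows are truncated at the image border. The result is non-negative
    (tiny negative values from floating-point cancellation are clipped).
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be an odd integer >= 3")
    a = np.asarray(image, dtype=np.float64)
    a = a - a.mean()  # shift-invariant; keeps constant images at exactly 0
    cnt = boxcar_count(np.ones(a.shape, dtype=bool), kernel).astype(np.float64)
    mean = boxcar_sum(a, kernel) / cnt
    meansq = boxcar_sum(a * a, kernel) / cnt
    return np.clip(meansq - mean * mean, 0.0, None)


def encode_slice(b, s: int):
    """Map a best-focus slice index b in [0, s-1] to an 8-bit grey value."""
    if s < 2:
        raise ValueError("s must be >= 2")
    b = np.asarray(b)
    if np.any(b < 0) or np.any(b > s - 1):
        raise ValueError("slice index out of range")
    return round_half_away(255.0 * b / (s - 1))


def decode_height(encoded, s: int, z_step_um: float):
    """Back-calculate the height (µm) encoded by an 8-bit height-map value.

    ``height = round(encoded * (s - 1) / 255) * Z`` with half-away-from-zero
    rounding, the exact inverse of :func:`encode_slice` on slice indices.
    """
    e = np.asarray(encoded, dtype=np.float64)
    if np.any(e < 0) or np.any(e > 255):
        raise ValueError("encoded values must lie in [0, 255]")
    b = round_half_away(e * (s - 1) / 255.0)
    out = b * z_step_um
    if np.ndim(encoded) == 0:
        return float(out)
    return out


def build_height_map(zstack: ZStack, kernel: int = 11) -> HeightMap:
    """Per-pixel argmax of the focus measure over slices, 8-bit encoded.

    Ties are broken toward the lower slice.
    """
    s = zstack.s
    best = np.zeros(zstack.shape, dtype=np.int32)
    best_score = np.full(zstack.shape, -1.0)
    for k in range(s):
        score = focus_measure(zstack.slices[k], kernel)
        better = score > best_score  # strict: ties keep the lower slice
        best[better] = k
        best_score[better] = score[better]
    encoded = encode_slice(best, s).astype(np.int32)
    valid = np.ones(zstack.shape, dtype=bool)
    return HeightMap(
        encoded=encoded, valid=valid, s=s,
        z_step_um=zstack.z_step_um, px_um=zstack.px_um,
    )


def build_edf(zstack: ZStack, heightmap: HeightMap) -> np.ndarray:
    """Extended-depth-of-focus composite: each pixel from its sharpest slice."""
    if heightmap.encoded.shape != zstack.shape:
        raise ValueError("height map dims must match slice dims")
    b = round_half_away(
        np.asarray(heightmap.encoded, dtype=np.float64) * (zstack.s - 1) / 255.0
    ).astype(np.intp)
    rows, cols = np.indices(zstack.shape)
    return np.asarray(zstack.slices)[b, rows, cols]
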
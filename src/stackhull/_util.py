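"""Shared numeric helpers: rounding convention and sliding-window sums.

The whole package uses a single rounding convention, round-half-away-from-zero,
because numpy's default banker's rounding would make the height-map encoding
depend on the parity of intermediate values.
"""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_away", "boxcar_sum", "boxcar_count"]


def round_half_away(x):
    """Round to nearest integer, halves away from zero.

    Works on scalars and arrays; returns a float array (or scalar) of whole
    numbers so callers can cast as needed.
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if out.ndim == 0:
        return float(out)
    return out


def _integral_image(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=a.dtype)
    np.cumsum(a, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def boxcar_sum(arr: np.ndarray, n: int, dtype=np.float64) -> np.ndarray:
    """Sliding n-by-n window sum with windows truncated at the image border.

    Uses an integral image, so cost is independent of ``n``. The window is
    centred on each pixel; at borders only the in-image part contributes
    (equivalent to zero padding).
    """
    if n < 1 or n % 2 == 0:
        raise ValueError("window size must be a positive odd integer")
    a = np.asarray(arr, dtype=dtype)
    h, w = a.shape
    r = n // 2
    s = _integral_image(a)
    i0 = np.clip(np.arange(h) - r, 0, h)
    i1 = np.clip(np.arange(h) + r + 1, 0, h)
    j0 = np.clip(np.arange(w) - r, 0, w)
    j1 = np.clip(np.arange(w) + r + 1, 0, w)
    return (
        s[np.ix_(i1, j1)] - s[np.ix_(i0, j1)] - s[np.ix_(i1, j0)] + s[np.ix_(i0, j0)]
    )


def boxcar_count(mask: np.ndarray, n: int) -> np.ndarray:
    """Number of True pixels in each truncated n-by-n window (exact, integer)."""
    return boxcar_sum(mask.astype(np.int64), n, dtype=np.int64)
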
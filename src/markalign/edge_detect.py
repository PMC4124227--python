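"""Sobel gradients, non-maximum suppression, and edge thinning.

The chain ``sobel_gradients -> non_max_suppress -> thin_edges`` turns a
smoothed gray image into a binary edge raster whose edges are (mostly) one
pixel wide, ready for circle-template matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import thin as _zs_thin

from .errors import DimensionError
from .image_core import as_gray

__all__ = [
    "SOBEL_MX",
    "SOBEL_MY",
    "GradientField",
    "sobel_gradients",
    "non_max_suppress",
    "thin_edges",
    "detect_edges",
]

# Horizontal (x) and vertical (y) Sobel masks, indexed [j, i].
SOBEL_MX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_MY = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.float64)


@dataclass(frozen=True)
class GradientField:
    """Per-pixel Sobel gradient components, magnitude, and direction.

    ``magnitude`` uses the ``|S_x| + |S_y|`` approximation of the total
    gradient.  ``theta_deg`` is the full-circle two-argument arctangent of
    ``(S_y, S_x)`` in degrees; ``theta_q`` is that angle rounded to the
    nearest multiple of 45 degrees, in ``{0, +/-45, +/-90, +/-135, 180}``.
    """

    sx: np.ndarray
    sy: np.ndarray
    magnitude: np.ndarray
    theta_deg: np.ndarray
    theta_q: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def sobel_gradients(img: np.ndarray) -> GradientField:
    """Compute Sobel gradients of *img* with replicated borders."""
    arr = as_gray(img)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise DimensionError(f"image must be at least 3x3, got {arr.shape}")
    sx = ndimage.correlate(arr, SOBEL_MX, mode="nearest")
    sy = ndimage.correlate(arr, SOBEL_MY, mode="nearest")
    mag = np.abs(sx) + np.abs(sy)
    theta = np.degrees(np.arctan2(sy, sx))
    q = np.round(theta / 45.0).astype(np.int64) * 45
    q[q == -180] = 180
    return GradientField(sx=sx, sy=sy, magnitude=mag, theta_deg=theta, theta_q=q)


# Quantized gradient direction -> (dx, dy) neighbor offset along the gradient.
_DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (1, 0),
    180: (1, 0),
    90: (0, 1),
    -90: (0, 1),
    45: (1, 1),
    -135: (1, 1),
    135: (1, -1),
    -45: (1, -1),
}


def non_max_suppress(grad: GradientField, threshold: float | str = "otsu") -> np.ndarray:
    """Suppress non-maximal gradient pixels, producing a prethinned edge map.

    A pixel survives when its magnitude exceeds *threshold* and is strictly
    greater than the magnitudes of both neighbors along the quantized
    gradient direction; ties suppress the pixel.  ``threshold="otsu"``
    derives a global cut from the magnitude histogram.
    """
    mag = grad.magnitude
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if mag.max() <= mag.min():
            return np.zeros(mag.shape, dtype=bool)
        thr = float(threshold_otsu(mag))
    else:
        thr = float(threshold)
        if thr < 0:
            raise ValueError(f"threshold must be non-negative, got {thr}")
    h, w = mag.shape
    padded = np.pad(mag, 1, mode="edge")
    n_fwd = np.empty_like(mag)
    n_bwd = np.empty_like(mag)
    for q, (dx, dy) in _DIRECTION_OFFSETS.items():
        sel = grad.theta_q == q
        if not sel.any():
            continue
        n_fwd[sel] = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w][sel]
        n_bwd[sel] = padded[1 - dy : 1 - dy + h, 1 - dx : 1 - dx + w][sel]
    return (mag > thr) & (mag > n_fwd) & (mag > n_bwd)


def thin_edges(prethinned: np.ndarray) -> np.ndarray:
    """Thin a binary edge image to one-pixel width.

    Iterative two-subiteration (Zhang-Suen style) thinning until stable;
    only removes pixels, never adds, and preserves connectivity.
    """
    arr = np.asarray(prethinned)
    if arr.dtype != bool:
        arr = arr.astype(bool)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D boolean image, got shape {arr.shape}")
    return _zs_thin(arr)


def detect_edges(
    img: np.ndarray, threshold: float | str = "otsu"
) -> np.ndarray:
    """Convenience chain: Sobel -> NMS -> thinning on a gray image."""
    return thin_edges(non_max_suppress(sobel_gradients(img), threshold))
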
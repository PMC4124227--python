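"""Grayscale image handling and Gaussian lowpass filtering.

Images are plain 2-D ``float64`` arrays indexed ``[y, x]`` (row-major,
origin at the top-left corner, *y* increasing downward).  Intensities live
on the 0–255 scale but stay real-valued through the pipeline; quantization
to 8-bit happens only when a file is written.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError

__all__ = [
    "rgb_to_gray",
    "GaussianMask",
    "make_gaussian_mask",
    "gaussian_filter",
    "as_gray",
    "read_image",
    "write_image",
]


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate and coerce *img* to a 2-D float64 intensity raster."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return rgb_to_gray(arr[:, :, :3])
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DimensionError(f"image dimensions must be positive, got {arr.shape}")
    return arr


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an ``(H, W, 3)`` color image to gray as the channel mean.

    Each output pixel is ``(R + G + B) / 3``, kept real-valued (no integer
    truncation).  Equal-weight averaging is deliberate; no luma weighting.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionError(
            f"expected an (H, W, 3) color image, got shape {arr.shape}"
        )
    return arr.mean(axis=2)


@dataclass(frozen=True)
class GaussianMask:
    """A ``D x D`` Gaussian smoothing kernel.

    Attributes
    ----------
    size:
        Odd kernel width ``D`` in pixels.
    sigma:
        Standard deviation in pixels.
    weights:
        The ``(D, D)`` weight array, indexed ``[j, i]`` with the kernel
        center at ``(size // 2, size // 2)``.
    normalized:
        Whether the weights were rescaled to sum to one.
    """

    size: int
    sigma: float
    weights: np.ndarray
    normalized: bool


def make_gaussian_mask(
    size: int = 5, sigma: float = 1.0, normalize: bool = True
) -> GaussianMask:
    """Build a square Gaussian mask of odd width *size*.

    With ``normalize=False`` the weights are the literal form
    ``G(i, j) = exp(-(i^2 + j^2) / (2 sigma^2)) / (2 N pi sigma^2)`` with
    ``N = size**2``; note this does *not* sum to one.  The default rescales
    the weights to unit sum so that smoothing preserves mean intensity.
    """
    if not isinstance(size, (int, np.integer)):
        raise ParameterError(f"mask size must be an integer, got {size!r}")
    if size < 1 or size % 2 == 0:
        raise ParameterError(f"mask size must be a positive odd integer, got {size}")
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    half = (size - 1) // 2
    ii, jj = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1))
    n_pixels = size * size
    w = np.exp(-(ii**2 + jj**2) / (2.0 * sigma**2)) / (2.0 * n_pixels * np.pi * sigma**2)
    if normalize:
        w = w / w.sum()
    return GaussianMask(size=int(size), sigma=float(sigma), weights=w, normalized=normalize)


def gaussian_filter(img: np.ndarray, mask: GaussianMask | None = None) -> np.ndarray:
    """Smooth *img* by correlation with *mask*, replicating border pixels.

    The output pixel at ``(x, y)`` is ``sum_ij G(i, j) * I(x+i, y+j)``.
    Out-of-bounds samples take the nearest edge pixel's value.
    """
    arr = as_gray(img)
    if mask is None:
        mask = make_gaussian_mask()
    if mask.size > min(arr.shape):
        raise DimensionError(
            f"mask size {mask.size} exceeds image dimensions {arr.shape}"
        )
    return ndimage.correlate(arr, mask.weights, mode="nearest")


# ---------------------------------------------------------------------------
# File I/O


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF image as a gray float array (RGB collapses to mean)."""
    p = os.fspath(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        arr = iio.imread(p)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        return rgb_to_gray(arr[:, :, :3].astype(np.float64))
    return arr.astype(np.float64)


def write_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write an image to PNG (8-bit, clipped) or TIFF (float32 preserved)."""
    p = os.fspath(path)
    arr = np.asarray(img)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(p, arr.astype(np.float32))
        return
    import imageio.v3 as iio

    if arr.dtype == bool:
        out = (arr * 255).astype(np.uint8)
    else:
        out = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    iio.imwrite(p, out)
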
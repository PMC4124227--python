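"""Chamber intensity tracing for liquid-replacement characterization.

Given a frame sequence and a chamber region of interest, compute per-frame
mean intensities, normalize between the start and end plateaus, and fit
the exponential replacement time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon

from .errors import DegenerateTraceError, DimensionError

__all__ = [
    "IntensityTrace",
    "disc_mask",
    "polygon_mask",
    "chamber_trace",
    "fit_time_constant",
    "replacement_time",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Normalized chamber-intensity trace over time."""

    times: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    label: str | None = None

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "raw": self.raw, "normalized": self.normalized}
        )


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean mask of a disc; *center* is (x, y) in pixels."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def polygon_mask(shape: tuple[int, int], vertices) -> np.ndarray:
    """Boolean mask of a polygon given ``[(x, y), ...]`` vertices."""
    verts = np.asarray(vertices, dtype=float)
    rr, cc = _draw_polygon(verts[:, 1], verts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def chamber_trace(
    frames: np.ndarray,
    times: np.ndarray | None = None,
    roi: np.ndarray | None = None,
    label: str | None = None,
    plateau_fraction: float = 0.05,
) -> IntensityTrace:
    """Mean-ROI intensity per frame, normalized between start/end plateaus.

    The plateaus are the means over the first and last ``plateau_fraction``
    of frames (at least one frame each); the normalized trace is 0 at the
    start plateau and 1 at the end plateau.  A vanishing plateau difference
    raises :class:`DegenerateTraceError`.
    """
    arr = np.asarray(frames, dtype=np.float64)
    if arr.ndim != 3:
        raise DimensionError(f"expected (n_frames, H, W) frames, got {arr.shape}")
    n = arr.shape[0]
    if n < 2:
        raise DimensionError("need at least 2 frames")
    if times is None:
        times = np.arange(n, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.shape != (n,):
        raise DimensionError("times length must match frame count")
    if roi is None:
        roi = np.ones(arr.shape[1:], dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != arr.shape[1:]:
        raise DimensionError(f"ROI shape {roi.shape} != frame shape {arr.shape[1:]}")
    if not roi.any():
        raise DimensionError("ROI is empty")
    raw = arr[:, roi].mean(axis=1)
    k = max(1, int(round(plateau_fraction * n)))
    start, end = raw[:k].mean(), raw[-k:].mean()
    span = end - start
    if abs(span) < 1e-9 * max(1.0, abs(start), abs(end)):
        raise DegenerateTraceError("start and end plateaus coincide; nothing to normalize")
    return IntensityTrace(times=times, raw=raw, normalized=(raw - start) / span, label=label)


def fit_time_constant(trace: IntensityTrace, window: tuple[float, float] = (0.05, 0.95)) -> float:
    """Fit the exponential time constant tau from a normalized trace.

    Log-linear least squares on ``log(1 - normalized)`` restricted to the
    *window* of normalized values, where the exponential is well resolved.
    """
    y = 1.0 - trace.normalized
    lo, hi = 1.0 - window[1], 1.0 - window[0]
    sel = (y > lo) & (y < hi)
    if sel.sum() < 2:
        raise DegenerateTraceError("too few points in the fitting window")
    slope, _ = np.polyfit(trace.times[sel], np.log(y[sel]), 1)
    if slope >= 0:
        raise DegenerateTraceError("trace does not decay toward its end plateau")
    return -1.0 / slope


def replacement_time(trace: IntensityTrace, fraction: float = 0.9) -> float:
    """First time at which the normalized change reaches *fraction*.

    Linear interpolation between the bracketing frames.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = trace.normalized
    above = np.nonzero(y >= fraction)[0]
    if len(above) == 0:
        raise DegenerateTraceError(f"trace never reaches {fraction:.0%} replacement")
    i = int(above[0])
    if i == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[i - 1], trace.times[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (fraction - y0) / (y1 - y0) * (t1 - t0))
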
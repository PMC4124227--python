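"""Synthetic chamber-view rendering with exact ground-truth poses.

Renders bright-field-like images of a three-circle alignment mark (dark
annuli on a bright background), optionally with a darker microwell disc,
at a continuous sub-pixel pose.  Anti-aliasing is done by supersampling so
the returned ground truth is meaningful below one pixel.  A small frame
generator emulating liquid replacement (exponential intensity exchange in
a chamber region) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RenderSpecError
from .mark_pose import MarkPose, assign_roles, estimate_pose

__all__ = ["RenderSpec", "MixingSpec", "render_mark_image", "render_mixing_frames",
           "triad_points"]


@dataclass(frozen=True)
class RenderSpec:
    """Parameters of one rendered chamber view.

    The mark reference (upper-left circle center) sits at the image center
    plus ``offset`` (pixels, sub-pixel allowed).  ``rotation_deg`` rotates
    the triad about the reference, positive clockwise on screen.  Circles
    are annuli of outer radius ``radius`` and stroke ``ring_width``.
    """

    shape: tuple[int, int] = (352, 352)  # (height, width)
    background: float = 200.0
    gradient: tuple[float, float] = (0.0, 0.0)  # intensity per px along (x, y)
    offset: tuple[float, float] = (0.0, 0.0)  # reference minus image center, px
    rotation_deg: float = 0.0
    radius: float = 10.0
    ring_width: float = 3.0
    spacing: float = 48.0
    ring_intensity: float = 60.0
    include_mark: bool = True
    well_radius: float = 0.0  # 0 disables the microwell disc
    well_intensity: float = 120.0
    well_offset: tuple[float, float] = (0.0, 0.0)  # well center minus image center
    noise_sigma: float = 0.0
    seed: int | None = None
    supersample: int = 4


def _center(shape: tuple[int, int]) -> tuple[float, float]:
    h, w = shape
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def triad_points(spec: RenderSpec) -> list[tuple[float, float]]:
    """Continuous-valued circle centers (c1, c2, c3) for *spec*."""
    cx, cy = _center(spec.shape)
    x1 = cx + spec.offset[0]
    y1 = cy + spec.offset[1]
    a = np.radians(spec.rotation_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    legs = [np.array([0.0, 0.0]), rot @ [spec.spacing, 0.0], rot @ [0.0, spec.spacing]]
    return [(x1 + v[0], y1 + v[1]) for v in legs]


def _coverage(shape, centers, r_outer, r_inner, ss):
    """Fraction of each pixel covered by any of the annuli, bbox-limited."""
    h, w = shape
    pad = r_outer + 2.0
    xs = [c[0] for c in centers]
    ys = [c[1] for c in centers]
    x0 = max(0, int(np.floor(min(xs) - pad)))
    x1 = min(w, int(np.ceil(max(xs) + pad)) + 1)
    y0 = max(0, int(np.floor(min(ys) - pad)))
    y1 = min(h, int(np.ceil(max(ys) + pad)) + 1)
    cov = np.zeros((h, w), dtype=np.float64)
    if x1 <= x0 or y1 <= y0:
        return cov
    sub = (np.arange((y1 - y0) * ss) + 0.5) / ss - 0.5 + y0
    suby = sub[:, None]
    subx = ((np.arange((x1 - x0) * ss) + 0.5) / ss - 0.5 + x0)[None, :]
    hit = np.zeros((suby.size, subx.size), dtype=bool)
    for cx, cy in centers:
        d2 = (subx - cx) ** 2 + (suby - cy) ** 2
        mask = d2 <= r_outer**2
        if r_inner > 0:
            mask &= d2 >= r_inner**2
        hit |= mask
    block = hit.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    cov[y0:y1, x0:x1] = block
    return cov


def render_mark_image(
    spec: RenderSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, MarkPose]:
    """Render a chamber view and return it with its exact ground-truth pose.

    Deterministic for a given ``spec.seed`` (or supplied *rng*).  Raises
    :class:`RenderSpecError` when the mark would not fit in the frame.
    """
    h, w = spec.shape
    if h < 8 or w < 8:
        raise RenderSpecError(f"frame {spec.shape} too small")
    if spec.noise_sigma < 0:
        raise RenderSpecError("noise_sigma must be non-negative")
    centers = triad_points(spec)
    if spec.include_mark:
        margin = spec.radius + 1.0
        for cx, cy in centers:
            if not (margin <= cx <= w - 1 - margin and margin <= cy <= h - 1 - margin):
                raise RenderSpecError(
                    f"mark circle at ({cx:.1f}, {cy:.1f}) leaves the {spec.shape} frame"
                )
    gx, gy = spec.gradient
    yy, xx = np.mgrid[0:h, 0:w]
    img = spec.background + gx * xx + gy * yy
    if spec.well_radius > 0:
        wc = _center(spec.shape)
        well = (wc[0] + spec.well_offset[0], wc[1] + spec.well_offset[1])
        cov = _coverage(spec.shape, [well], spec.well_radius, 0.0, spec.supersample)
        img = img + cov * (spec.well_intensity - img)
    if spec.include_mark:
        r_in = max(spec.radius - spec.ring_width, 0.0)
        cov = _coverage(spec.shape, centers, spec.radius, r_in, spec.supersample)
        img = img + cov * (spec.ring_intensity - img)
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    np.clip(img, 0.0, 255.0, out=img)
    triad = assign_roles(centers)
    truth = estimate_pose(triad)
    return img, truth


@dataclass(frozen=True)
class MixingSpec:
    """Parameters of a synthetic liquid-replacement frame sequence.

    Chamber intensity follows ``I(t) = I_end + (I_start - I_end) * exp(-t/tau)``;
    ``direction="extraction"`` swaps the start/end intensities.
    """

    tau_s: float = 3.0
    frame_interval_s: float = 0.5
    n_frames: int = 60
    lead_in_s: float = 0.0  # pre-exchange plateau duration
    direction: str = "injection"
    intensity_start: float = 210.0
    intensity_end: float = 70.0
    background: float = 230.0
    shape: tuple[int, int] = (48, 48)
    well_radius: float = 16.0
    noise_sigma: float = 0.0
    seed: int | None = None
    label: str | None = None


def render_mixing_frames(
    spec: MixingSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render ``(times, frames)`` for a liquid-replacement sequence."""
    if spec.tau_s <= 0:
        raise RenderSpecError("tau_s must be positive")
    if spec.n_frames < 2:
        raise RenderSpecError("need at least 2 frames")
    if spec.direction not in ("injection", "extraction"):
        raise RenderSpecError(f"unknown direction {spec.direction!r}")
    i0, i1 = spec.intensity_start, spec.intensity_end
    if spec.direction == "extraction":
        i0, i1 = i1, i0
    times = np.arange(spec.n_frames) * spec.frame_interval_s
    h, w = spec.shape
    cov = _coverage(spec.shape, [_center(spec.shape)], spec.well_radius, 0.0, 4)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, h, w), dtype=np.float64)
    for k, t in enumerate(times):
        t_exch = max(t - spec.lead_in_s, 0.0)
        level = i1 + (i0 - i1) * np.exp(-t_exch / spec.tau_s)
        frame = spec.background + cov * (level - spec.background)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[k] = np.clip(frame, 0.0, 255.0)
    return times, frames
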
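"""Tri-valued circle templates and the normalized edge-match map.

A template is a small square raster whose pixels are *white* (full weight
1), *gray* (partial weight ``g``), or *black* (excluded, weight 0).  The
match score at an image position is the weight-sum of edge pixels under the
centered template divided by the total template weight, giving a value in
``[0, 1]``.  The three strongest well-separated peaks of that map locate
the circles of one alignment mark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from skimage.draw import circle_perimeter

from .errors import DetectionFailureError, DimensionError, ParameterError

__all__ = [
    "TemplateImage",
    "CircleTriad",
    "make_circle_template",
    "match_template",
    "find_circle_triad",
    "refine_peak",
]


@dataclass(frozen=True)
class TemplateImage:
    """A circle matching template.

    ``weights`` is the ``(D_T, D_T)`` array of per-pixel weights: 1.0 on the
    rasterized circle of radius ``radius``, ``gray_weight`` on the adjacent
    inner/outer rings for the ``"gray_boundary"`` variant, 0 elsewhere
    (excluded pixels).  The circle is centered at ``(D_T // 2, D_T // 2)``.
    """

    weights: np.ndarray
    radius: int
    variant: str
    gray_weight: float

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @property
    def weight_sum(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class CircleTriad:
    """Centers and scores of the three detected circles.

    ``c1``, ``c2``, ``c3`` are ``(x, y)`` pixel coordinates of the
    upper-left, right, and lower circles respectively.
    """

    c1: tuple[float, float]
    c2: tuple[float, float]
    c3: tuple[float, float]
    scores: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def centers(self) -> tuple[tuple[float, float], ...]:
        return (self.c1, self.c2, self.c3)


def make_circle_template(
    radius: int, variant: str = "gray_boundary", gray_weight: float = 0.5
) -> TemplateImage:
    """Build a circle template of pixel radius *radius*.

    The template is ``(2*radius + 5)`` pixels square: the midpoint-rasterized
    circle, optional one-pixel gray rings at ``radius - 1`` and
    ``radius + 1``, and a margin of excluded pixels.
    """
    if radius < 2:
        raise ParameterError(f"template radius must be >= 2, got {radius}")
    if variant not in ("white_only", "gray_boundary"):
        raise ParameterError(f"unknown template variant {variant!r}")
    if not 0.0 < gray_weight <= 1.0:
        raise ParameterError(f"gray weight must be in (0, 1], got {gray_weight}")
    size = 2 * radius + 5
    c = size // 2
    w = np.zeros((size, size), dtype=np.float64)
    rr, cc = circle_perimeter(c, c, radius, shape=(size, size))
    white = np.zeros((size, size), dtype=bool)
    white[rr, cc] = True
    w[white] = 1.0
    if variant == "gray_boundary":
        gray = np.zeros((size, size), dtype=bool)
        for r in (radius - 1, radius + 1):
            rr, cc = circle_perimeter(c, c, r, shape=(size, size))
            gray[rr, cc] = True
        gray &= ~white
        w[gray] = gray_weight
    return TemplateImage(weights=w, radius=int(radius), variant=variant,
                         gray_weight=float(gray_weight))


def match_template(edges: np.ndarray, tmpl: TemplateImage) -> np.ndarray:
    """Compute the normalized match map of *edges* against *tmpl*.

    ``C(x, y)`` is the weighted count of edge pixels under the template
    centered at ``(x, y)``, divided by the template weight sum.  Positions
    where the template would overhang the image border score 0.
    """
    e = np.asarray(edges, dtype=np.float64)
    if e.ndim != 2:
        raise DimensionError(f"expected a 2-D edge image, got shape {e.shape}")
    size = tmpl.size
    if size > e.shape[0] or size > e.shape[1]:
        raise DimensionError(
            f"template size {size} exceeds edge image shape {e.shape}"
        )
    c = size // 2
    valid = signal.correlate(e, tmpl.weights, mode="valid", method="fft")
    valid /= tmpl.weight_sum
    out = np.zeros_like(e)
    out[c : c + valid.shape[0], c : c + valid.shape[1]] = valid
    np.clip(out, 0.0, 1.0, out=out)
    return out


def refine_peak(cmap: np.ndarray, x: int, y: int) -> tuple[float, float]:
    """Sub-pixel refinement: center of mass of the 3x3 neighborhood of a peak."""
    h, w = cmap.shape
    y0, y1 = max(0, y - 1), min(h, y + 2)
    x0, x1 = max(0, x - 1), min(w, x + 2)
    win = cmap[y0:y1, x0:x1]
    total = win.sum()
    if total <= 0:
        return float(x), float(y)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return float((win * xs).sum() / total), float((win * ys).sum() / total)


def find_circle_triad(
    cmap: np.ndarray,
    exclusion_radius: float,
    floor_score: float = 0.3,
    refine: bool = True,
) -> CircleTriad:
    """Locate the three strongest well-separated peaks of a match map.

    Peaks are taken greedily: the global maximum, then the maximum outside
    an exclusion disc around each prior peak.  Ties break toward smaller
    ``(y, x)``.  Peaks below *floor_score* raise
    :class:`DetectionFailureError`.  Roles (upper-left / right / lower) are
    assigned geometrically; see :func:`markalign.mark_pose.assign_roles`.
    """
    work = np.array(cmap, dtype=np.float64, copy=True)
    h, w = work.shape
    ys, xs = np.mgrid[0:h, 0:w]
    peaks: list[tuple[float, float]] = []
    scores: list[float] = []
    for k in range(3):
        idx = int(np.argmax(work))  # row-major argmax => smallest (y, x) tie-break
        py, px = divmod(idx, w)
        score = float(work[py, px])
        if score < floor_score:
            raise DetectionFailureError(
                f"only {k} peak(s) above floor score {floor_score}; "
                f"next candidate scored {score:.3f}"
            )
        if refine:
            peaks.append(refine_peak(cmap, px, py))
        else:
            peaks.append((float(px), float(py)))
        scores.append(score)
        work[(xs - px) ** 2 + (ys - py) ** 2 <= exclusion_radius**2] = -np.inf
    from .mark_pose import assign_roles  # deferred to avoid import cycle

    return assign_roles(peaks, scores=tuple(scores))
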
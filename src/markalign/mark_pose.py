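"""Triad role assignment, mark pose estimation, and position error.

Coordinates are image pixels: *x* rightward, *y* downward.  Angles are
degrees, positive clockwise on screen (the natural sign of
``atan2(dy, dx)`` in y-down coordinates), so an unrotated mark — second
circle due right of the first, third circle due below — reads 0 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import RoleAssignmentError
from .template_match import CircleTriad

__all__ = ["MarkPose", "AlignmentError", "assign_roles", "estimate_pose",
           "position_error", "DEFAULT_PIXEL_WIDTH_UM"]

#: Default physical pixel width, micrometers per pixel.
DEFAULT_PIXEL_WIDTH_UM = 0.94


@dataclass(frozen=True)
class MarkPose:
    """Detected mark pose: reference point, orientation, and triad."""

    x_ref: float
    y_ref: float
    theta_deg: float
    triad: CircleTriad

    @property
    def reference(self) -> tuple[float, float]:
        return (self.x_ref, self.y_ref)

    def to_record(self) -> dict:
        return {
            "x_ref": self.x_ref,
            "y_ref": self.y_ref,
            "theta_deg": self.theta_deg,
            "scores": list(self.triad.scores),
            "centers": [list(c) for c in self.triad.centers],
        }


@dataclass(frozen=True)
class AlignmentError:
    """A chamber position error in pixels and micrometers."""

    e_px: float
    e_um: float


def _dist_point_line(p, a, b) -> float:
    ab = np.subtract(b, a)
    ap = np.subtract(p, a)
    norm = float(np.hypot(*ab))
    if norm == 0:
        return float(np.hypot(*ap))
    return abs(float(ab[0] * ap[1] - ab[1] * ap[0])) / norm


def assign_roles(
    centers: Sequence[tuple[float, float]],
    scores: tuple[float, float, float] | None = None,
    collinear_tol: float = 2.0,
) -> CircleTriad:
    """Assign upper-left / right / lower roles to three circle centers.

    ``c1`` is the point minimizing ``x + y``; of the remaining two, ``c2``
    is the one with larger ``x - y`` (rightward) and ``c3`` the other
    (downward).  The rule is stable for mark rotations within roughly
    +/-30 degrees.  Near-collinear or ambiguous inputs raise
    :class:`RoleAssignmentError`.
    """
    pts = [(float(x), float(y)) for x, y in centers]
    if len(pts) != 3:
        raise RoleAssignmentError(f"expected exactly 3 centers, got {len(pts)}")
    if len({p for p in pts}) != 3:
        raise RoleAssignmentError("centers must be distinct")
    for k in range(3):
        others = [pts[m] for m in range(3) if m != k]
        if _dist_point_line(pts[k], *others) < collinear_tol:
            raise RoleAssignmentError(
                f"centers are collinear within {collinear_tol} px: {pts}"
            )
    sums = [x + y for x, y in pts]
    order = sorted(range(3), key=lambda k: sums[k])
    if abs(sums[order[0]] - sums[order[1]]) < 1e-9:
        raise RoleAssignmentError(f"ambiguous upper-left circle among {pts}")
    i1 = order[0]
    rest = [k for k in range(3) if k != i1]
    diffs = [pts[k][0] - pts[k][1] for k in rest]
    if abs(diffs[0] - diffs[1]) < 1e-9:
        raise RoleAssignmentError(f"ambiguous right/lower circles among {pts}")
    if diffs[0] > diffs[1]:
        i2, i3 = rest
    else:
        i3, i2 = rest
    s = scores if scores is not None else (0.0, 0.0, 0.0)
    return CircleTriad(c1=pts[i1], c2=pts[i2], c3=pts[i3],
                       scores=(s[i1], s[i2], s[i3]))


def estimate_pose(triad: CircleTriad) -> MarkPose:
    """Estimate the mark reference position and orientation from a triad.

    The reference is the upper-left circle center.  Orientation averages
    the angle of the c1->c2 leg with the angle of the c1->c3 leg minus its
    90-degree baseline, both via two-argument arctangent, so an unrotated
    mark yields exactly 0.
    """
    (x1, y1), (x2, y2), (x3, y3) = triad.c1, triad.c2, triad.c3
    a12 = np.degrees(np.arctan2(y2 - y1, x2 - x1))
    a13 = np.degrees(np.arctan2(y3 - y1, x3 - x1))
    theta = 0.5 * (a12 + (a13 - 90.0))
    return MarkPose(x_ref=x1, y_ref=y1, theta_deg=float(theta), triad=triad)


def position_error(
    detected: MarkPose | tuple[float, float],
    target: tuple[float, float],
    pixel_width: float = DEFAULT_PIXEL_WIDTH_UM,
) -> AlignmentError:
    """Euclidean distance between detected reference and target, in px and um."""
    if isinstance(detected, MarkPose):
        ref = detected.reference
    else:
        ref = (float(detected[0]), float(detected[1]))
    e_px = float(np.hypot(ref[0] - target[0], ref[1] - target[1]))
    return AlignmentError(e_px=e_px, e_um=e_px * pixel_width)
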
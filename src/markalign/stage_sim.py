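"""Virtual motorized xy stage and device geometry.

The simulator keeps two positions: what the controller *believes* (the sum
of commanded displacements) and where the stage truly is.  They diverge
through three phenomenological error terms — per-move Gaussian noise whose
standard deviation has a fixed part plus a distance-proportional part, a
systematic pitch (scale) bias on every commanded displacement, and a
per-scan drift increment standing in for device dislocation (tubing pull,
loosened fixation, vibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic_data import RenderSpec, render_mark_image
from .errors import ParameterError

__all__ = [
    "DeviceGeometry",
    "NoiseModel",
    "StageState",
    "ScanRecord",
    "make_stage",
    "move_stage",
    "apply_drift",
    "serpentine_path",
    "capture_view",
    "mark_offset_px",
]


@dataclass(frozen=True)
class DeviceGeometry:
    """Chamber grid and alignment-mark geometry, in micrometers."""

    rows: int = 4
    cols: int = 8
    pitch_x_um: float = 2000.0
    pitch_y_um: float = 2000.0
    mark_to_chamber_um: tuple[float, float] = (1200.0, 1200.0)
    pixel_width_um: float = 0.94
    mark_radius_um: float = 9.4
    mark_ring_width_um: float = 2.82
    mark_spacing_um: float = 45.12

    @property
    def n_chambers(self) -> int:
        return self.rows * self.cols

    @property
    def mark_radius_px(self) -> float:
        return self.mark_radius_um / self.pixel_width_um

    @property
    def mark_spacing_px(self) -> float:
        return self.mark_spacing_um / self.pixel_width_um

    def mark_position_um(self, row: int, col: int) -> np.ndarray:
        """Nominal world position of the chamber's alignment mark."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ParameterError(
                f"chamber ({row}, {col}) outside {self.rows}x{self.cols} grid"
            )
        return np.array([col * self.pitch_x_um, row * self.pitch_y_um])


@dataclass(frozen=True)
class NoiseModel:
    """Stage error model.

    Per-axis noise sd for a move of length L is
    ``sigma_move_um + sigma_rel * L``; every commanded displacement is
    scaled by ``1 + pitch_bias``; ``drift_um`` is added to the true
    position once per scan (see :func:`apply_drift`).
    """

    sigma_move_um: float = 0.5
    sigma_rel: float = 0.0005
    pitch_bias: float = 0.003
    drift_um: tuple[float, float] = (10.0, 8.0)


@dataclass
class StageState:
    """Virtual stage pose: hidden true position vs controller belief."""

    true_um: np.ndarray
    believed_um: np.ndarray
    noise: NoiseModel
    rng: np.random.Generator = field(repr=False)


def make_stage(
    noise: NoiseModel | None = None,
    seed: int | None = None,
    position_um: tuple[float, float] = (0.0, 0.0),
) -> StageState:
    """Create a stage with true == believed at *position_um*."""
    pos = np.asarray(position_um, dtype=np.float64)
    return StageState(
        true_um=pos.copy(),
        believed_um=pos.copy(),
        noise=noise if noise is not None else NoiseModel(),
        rng=np.random.default_rng(seed),
    )


def move_stage(state: StageState, displacement_um) -> StageState:
    """Command a relative move; returns a new state (rng stream is shared).

    The believed position advances by the displacement exactly; the true
    position advances by ``displacement * (1 + pitch_bias)`` plus per-axis
    Gaussian noise.
    """
    d = np.asarray(displacement_um, dtype=np.float64)
    if d.shape != (2,) or not np.all(np.isfinite(d)):
        raise ParameterError(f"displacement must be a finite 2-vector, got {d!r}")
    n = state.noise
    length = float(np.hypot(*d))
    sd = n.sigma_move_um + n.sigma_rel * length
    jitter = state.rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
    return replace(
        state,
        true_um=state.true_um + d * (1.0 + n.pitch_bias) + jitter,
        believed_um=state.believed_um + d,
    )


def apply_drift(state: StageState, steps: int = 1) -> StageState:
    """Apply *steps* increments of per-scan device dislocation drift."""
    drift = np.asarray(state.noise.drift_um, dtype=np.float64) * steps
    return replace(state, true_um=state.true_um + drift)


def serpentine_path(geometry: DeviceGeometry, scan_index: int = 0) -> list[tuple[int, int]]:
    """Boustrophedon chamber order for one scan.

    Even ``scan_index`` (1st, 3rd, ... scan) traverses rows alternating
    left-to-right / right-to-left starting at (0, 0); odd ``scan_index``
    is the exact reverse, so consecutive scans join end-to-start.
    """
    path: list[tuple[int, int]] = []
    for r in range(geometry.rows):
        cols = range(geometry.cols) if r % 2 == 0 else range(geometry.cols - 1, -1, -1)
        path.extend((r, c) for c in cols)
    if scan_index % 2 == 1:
        path.reverse()
    return path


def mark_offset_px(
    state: StageState, geometry: DeviceGeometry, chamber: tuple[int, int]
) -> np.ndarray:
    """True mark offset from the image center, pixels (hidden ground truth)."""
    mark = geometry.mark_position_um(*chamber)
    return (state.true_um - mark) / geometry.pixel_width_um


def capture_view(
    state: StageState,
    geometry: DeviceGeometry,
    chamber: tuple[int, int],
    frame_px: int = 352,
    noise_sigma: float = 4.0,
    rng: np.random.Generator | None = None,
):
    """Render the camera view of a chamber's alignment mark.

    The mark appears displaced from the image center by the true stage
    positioning error converted to pixels.  Rendering noise draws from the
    stage's rng unless an explicit generator is given, keeping whole-run
    reproducibility under one seed.
    """
    offset = mark_offset_px(state, geometry, chamber)
    spec = RenderSpec(
        shape=(frame_px, frame_px),
        offset=(float(offset[0]), float(offset[1])),
        radius=geometry.mark_radius_px,
        ring_width=geometry.mark_ring_width_um / geometry.pixel_width_um,
        spacing=geometry.mark_spacing_px,
        noise_sigma=noise_sigma,
    )
    img, truth = render_mark_image(spec, rng=rng if rng is not None else state.rng)
    return img, truth


@dataclass(frozen=True)
class ScanRecord:
    """Per-chamber outcome of one visit during a scan."""

    scan_index: int
    row: int
    col: int
    e_px: float
    e_um: float
    aligned: bool
    iterations: int
    pre_e_px: float = np.nan
    theta_deg: float = np.nan
    detect_failed: bool = False
    measured_by: str = "detect"
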
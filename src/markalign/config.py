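"""Nested run configuration with strict key validation and YAML loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .align_control import AlignmentConfig, DetectionParams
from .errors import ConfigError
from .stage_sim import DeviceGeometry, NoiseModel

__all__ = ["RunConfig"]


@dataclass
class GaussianSection:
    size: int = 5
    sigma: float = 1.0
    normalize: bool = True


@dataclass
class EdgeSection:
    threshold: float | str = "otsu"


@dataclass
class TemplateSection:
    radius: int = 10
    variant: str = "gray_boundary"
    gray_weight: float = 0.5
    exclusion_radius: float | None = None
    floor_score: float = 0.15


@dataclass
class StageSection:
    sigma_move_um: float = 0.5
    sigma_rel: float = 0.0005
    pitch_bias: float = 0.003
    drift_um: tuple[float, float] = (10.0, 8.0)


@dataclass
class GeometrySection:
    rows: int = 4
    cols: int = 8
    pitch_x_um: float = 2000.0
    pitch_y_um: float = 2000.0
    mark_to_chamber_um: tuple[float, float] = (1200.0, 1200.0)
    pixel_width_um: float = 0.94
    mark_radius_um: float = 9.4
    mark_ring_width_um: float = 2.82
    mark_spacing_um: float = 45.12


@dataclass
class AlignmentSection:
    tolerance_px: float = 3.0
    max_iterations: int = 5
    update_distances: bool = True


@dataclass
class RenderSection:
    frame_px: int = 352
    background: float = 200.0
    ring_intensity: float = 60.0
    noise_sigma: float = 4.0


def _fill(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid values under '{path}': {exc}") from exc


@dataclass
class RunConfig:
    """Validated nested configuration binding all pipeline modules."""

    gaussian: GaussianSection = field(default_factory=GaussianSection)
    edge: EdgeSection = field(default_factory=EdgeSection)
    template: TemplateSection = field(default_factory=TemplateSection)
    stage: StageSection = field(default_factory=StageSection)
    geometry: GeometrySection = field(default_factory=GeometrySection)
    alignment: AlignmentSection = field(default_factory=AlignmentSection)
    render: RenderSection = field(default_factory=RenderSection)
    seed: int = 0

    _SECTIONS = {
        "gaussian": GaussianSection,
        "edge": EdgeSection,
        "template": TemplateSection,
        "stage": StageSection,
        "geometry": GeometrySection,
        "alignment": AlignmentSection,
        "render": RenderSection,
    }

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        cfg = cls()
        seed = data.pop("seed", cfg.seed)
        unknown = set(data) - set(cls._SECTIONS)
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            sub = data.get(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _fill(section_cls, sub, name)
        return cls(seed=seed, **kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    # -- adapters to module-level parameter objects -------------------------

    def device_geometry(self) -> DeviceGeometry:
        return DeviceGeometry(**dataclasses.asdict(self.geometry))

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            sigma_move_um=self.stage.sigma_move_um,
            sigma_rel=self.stage.sigma_rel,
            pitch_bias=self.stage.pitch_bias,
            drift_um=tuple(self.stage.drift_um),
        )

    def alignment_config(self) -> AlignmentConfig:
        return AlignmentConfig(
            tolerance_px=self.alignment.tolerance_px,
            max_iterations=self.alignment.max_iterations,
            pixel_width_um=self.geometry.pixel_width_um,
            update_distances=self.alignment.update_distances,
        )

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            gaussian_size=self.gaussian.size,
            gaussian_sigma=self.gaussian.sigma,
            edge_threshold=self.edge.threshold,
            template_radius=self.template.radius,
            template_variant=self.template.variant,
            gray_weight=self.template.gray_weight,
            exclusion_radius=self.template.exclusion_radius,
            floor_score=self.template.floor_score,
        )
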
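"""Pipeline configuration: thresholds, camera profiles, station switches.

Defaults reproduce the production settings of the sorting machine: the
81,900-124,500 px^2 size gate (~300-450 mm^2 at ~273 px^2/mm^2), the two
fixed HSB stain profiles, the 144 px^2 per-object stain rule, a 70/30 shape
split and an 80/20 alive/dead split, both cross-validated over 100
iterations.  Configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ValidationError
from .imaging import DEFAULT_EPS, SizeThresholds
from .stains import BOTTOM_PROFILE, TOP_PROFILE, StainProfile


@dataclass(frozen=True)
class ImagingConfig:
    eps: float = DEFAULT_EPS
    foreground: str = "center"  # Otsu polarity: center | above | below
    connectivity: int = 2
    outline_points: int = 180


@dataclass(frozen=True)
class ShapeModelConfig:
    n_harmonics: int = 90  # Nyquist order for 180 outline points
    power_fraction: float = 0.99999
    train_fraction: float = 0.7
    cv_iterations: int = 100
    balance_mode: str = "once"  # once | per_iteration | none
    # classical chord-length parameterization: robust to the uneven point
    # spacing the equal-angle digitizer produces on elongated silhouettes
    efa_method: str = "chord"


@dataclass(frozen=True)
class VitalModelConfig:
    train_fraction: float = 0.8
    cv_iterations: int = 100


@dataclass(frozen=True)
class StainConfig:
    top: StainProfile = TOP_PROFILE
    bottom: StainProfile = BOTTOM_PROFILE
    restrict_to_cocoon: bool = True


@dataclass(frozen=True)
class StationSwitches:
    size: bool = True
    shape: bool = True
    stain: bool = True
    vital: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    size: SizeThresholds = field(
        default_factory=lambda: SizeThresholds(81_900, 124_500, 273.0)
    )
    stain: StainConfig = field(default_factory=StainConfig)
    shape_model: ShapeModelConfig = field(default_factory=ShapeModelConfig)
    vital_model: VitalModelConfig = field(default_factory=VitalModelConfig)
    stations: StationSwitches = field(default_factory=StationSwitches)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def profile(p: dict, default: StainProfile) -> StainProfile:
            merged = {**asdict(default), **(p or {})}
            for key in ("h_range", "s_range", "b_range"):
                merged[key] = tuple(merged[key])
            return StainProfile(**merged)

        stain_d = d.get("stain", {}) or {}
        return cls(
            imaging=ImagingConfig(**(d.get("imaging", {}) or {})),
            size=SizeThresholds(**(d.get("size", {}) or asdict(cls().size))),
            stain=StainConfig(
                top=profile(stain_d.get("top", {}), TOP_PROFILE),
                bottom=profile(stain_d.get("bottom", {}), BOTTOM_PROFILE),
                restrict_to_cocoon=stain_d.get("restrict_to_cocoon", True),
            ),
            shape_model=ShapeModelConfig(**(d.get("shape_model", {}) or {})),
            vital_model=VitalModelConfig(**(d.get("vital_model", {}) or {})),
            stations=StationSwitches(**(d.get("stations", {}) or {})),
        )


def load_config(path=None) -> PipelineConfig:
    """Load a YAML pipeline configuration; ``None`` returns the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: top-level YAML must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
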
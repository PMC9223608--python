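"""Single-file pipeline configuration with strict validation.

Every stage parameter lives in one YAML-serializable dataclass tree.  An
empty file yields all defaults; unknown keys and out-of-order z thresholds
are rejected, and a write/read round trip is lossless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ScreenConfig",
    "ImagingConfig",
    "CalciumConfig",
    "PathwayConfig",
    "ScoringConfig",
    "PipelineConfig",
    "validate_config",
]


@dataclass
class ScreenConfig:
    n_drugs: int = 41
    top_conc_M: float = 3.0e-5
    fold: float = 4.0
    n_points: int = 7
    n_replicates: int = 2
    n_vehicle: int = 8
    sigma: float = 0.05
    hit_drug: str | None = "drug_07"
    hit_ic50: float = 1.0e-7
    hit_bottom: float = 0.0
    hit_hill: float = 1.0


@dataclass
class ImagingConfig:
    n_samples: int = 2
    n_cells: int = 10
    image_height: int = 512
    image_width: int = 512
    n_z: int = 5
    vital_k: float = 3.0
    footprint_k: float = 0.5
    nuclei_sigma: float = 2.0
    network_scales: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0])
    network_k: float = 3.0


@dataclass
class CalciumConfig:
    n_cells: int = 12
    duration_s: float = 600.0
    frame_interval_s: float = 1.52
    rate_per_min: float = 1.0
    amplitude: float = 0.8
    noise_sd: float = 0.05
    smoothing_sigma: float = 2.0
    min_prominence: float = 0.1
    tolerance_frames: float = 2.0


@dataclass
class PathwayConfig:
    n_samples: int = 20
    n_pathways_per_block: int = 4
    genes_per_pathway: int = 15
    n_background_genes: int = 200
    alpha: float = 0.25
    cluster_k: int = 3
    response_score: str = "negated_auc"  # or "raw_auc"


@dataclass
class ScoringConfig:
    positive_control: str = "bortezomib"
    z_strong: float = -1.0
    z_weak: float = -0.5


@dataclass
class PipelineConfig:
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    pathways: PathwayConfig = field(default_factory=PathwayConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def validate(self) -> "PipelineConfig":
        if self.scoring.z_strong >= self.scoring.z_weak:
            raise ValueError(
                "thresholds out of order: z_strong must be below z_weak "
                f"(got {self.scoring.z_strong} >= {self.scoring.z_weak})"
            )
        if self.pathways.response_score not in ("negated_auc", "raw_auc"):
            raise ValueError(
                f"unknown response_score {self.pathways.response_score!r}"
            )
        if self.screen.n_points < 2 or self.screen.fold <= 1:
            raise ValueError("screen needs n_points >= 2 and fold > 1")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if dataclasses.is_dataclass(_SECTION_TYPES.get(name)) and isinstance(value, dict):
            kwargs[name] = _build(_SECTION_TYPES[name], value, f"{path}{name}.")
        elif isinstance(value, dict):
            raise ValueError(f"config key {path}{name} does not take a mapping")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "screen": ScreenConfig,
    "imaging": ImagingConfig,
    "calcium": CalciumConfig,
    "pathways": PathwayConfig,
    "scoring": ScoringConfig,
}


def validate_config(path: str | None = None, data: dict | None = None) -> PipelineConfig:
    """Load + normalize a config file; defaults fill everything not given."""
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    cfg = _build(PipelineConfig, data, "")
    return cfg.validate()
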
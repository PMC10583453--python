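"""Pipeline configuration: one YAML-serializable object whose sections
mirror the pipeline stages, with a single master seed from which all stage
seeds derive.

The default configuration is desk-scale (48x48x24 grid, 60 subjects,
40 epochs) so the full pipeline runs in minutes on one CPU;
``PipelineConfig.full_scale()`` carries the full-scale study geometry and
training recipe (240x240x155 template, 118 subjects, 100 epochs, crop
40/25, batch 16, learning rate 3e-4, thresholds 0.1..0.6).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash",
           "derive_seeds"]


@dataclasses.dataclass
class CohortSection:
    n_short: int = 21
    n_medium: int = 15
    n_long: int = 24
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    n_regions: int = 12
    coupling: float = 1.0
    tumor_radius_frac: float = 0.18
    radius_jitter_sd: float = 0.10


@dataclasses.dataclass
class CropSection:
    n_inferior: int = 4
    n_superior: int = 2


@dataclasses.dataclass
class ClassBinsSection:
    month_divisor: float = 30.44


@dataclasses.dataclass
class ModelSection:
    filters_per_block: tuple[int, int, int] = (6, 16, 32)
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool: int = 2
    dropout: float = 0.2


@dataclasses.dataclass
class TrainSection:
    batch_size: int = 16
    max_epochs: int = 40
    learning_rate: float = 3e-4
    momentum: float = 0.9
    augment: bool = True
    max_rotation_deg: float = 10.0
    max_translation_vox: int = 5


@dataclasses.dataclass
class GradcamSection:
    use_probability: bool = False


@dataclasses.dataclass
class ProbmapsSection:
    epsilon: float = 1e-8


@dataclasses.dataclass
class AttributionSection:
    thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    min_voxels: int = 1


@dataclasses.dataclass
class PredictionSection:
    threshold: float = 0.3
    binarized_dice: bool = False


@dataclasses.dataclass
class EvaluationSection:
    thresholds: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    min_class_n: int = 3


_SECTION_TYPES = {
    "cohort": CohortSection,
    "crop": CropSection,
    "class_bins": ClassBinsSection,
    "model": ModelSection,
    "train": TrainSection,
    "gradcam": GradcamSection,
    "probmaps": ProbmapsSection,
    "attribution": AttributionSection,
    "prediction": PredictionSection,
    "evaluation": EvaluationSection,
}


@dataclasses.dataclass
class PipelineConfig:
    cohort: CohortSection = dataclasses.field(default_factory=CohortSection)
    crop: CropSection = dataclasses.field(default_factory=CropSection)
    class_bins: ClassBinsSection = dataclasses.field(default_factory=ClassBinsSection)
    model: ModelSection = dataclasses.field(default_factory=ModelSection)
    train: TrainSection = dataclasses.field(default_factory=TrainSection)
    gradcam: GradcamSection = dataclasses.field(default_factory=GradcamSection)
    probmaps: ProbmapsSection = dataclasses.field(default_factory=ProbmapsSection)
    attribution: AttributionSection = dataclasses.field(
        default_factory=AttributionSection)
    prediction: PredictionSection = dataclasses.field(
        default_factory=PredictionSection)
    evaluation: EvaluationSection = dataclasses.field(
        default_factory=EvaluationSection)
    seed: int = 0

    @classmethod
    def full_scale(cls) -> "PipelineConfig":
        """Full-scale study geometry and training recipe."""
        cfg = cls()
        cfg.cohort = CohortSection(n_short=42, n_medium=30, n_long=46,
                                   grid_shape=(240, 240, 155), n_regions=56)
        cfg.crop = CropSection(n_inferior=40, n_superior=25)
        cfg.train = TrainSection(max_epochs=100)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(section_cls, raw: dict):
    fields = {f.name: f for f in dataclasses.fields(section_cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown keys in section {section_cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return section_cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Every section must be present; a missing section is a validation error
    naming that section.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    missing = [name for name in list(_SECTION_TYPES) + ["seed"] if name not in raw]
    if missing:
        raise ValueError(f"config missing sections: {missing}")
    sections = {name: _coerce(cls, raw[name] or {})
                for name, cls in _SECTION_TYPES.items()}
    return PipelineConfig(seed=int(raw["seed"]), **sections)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(json.loads(json.dumps(config.to_dict())),
                                   sort_keys=True))
    return path


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the resolved configuration, stamped on artifacts."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def derive_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    """One deterministic sub-seed per named stage from the master seed."""
    seeds = {}
    for i, name in enumerate(names):
        ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(i,))
        seeds[name] = int(ss.generate_state(1)[0] % (2 ** 31))
    return seeds
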
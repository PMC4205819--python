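"""Pipeline configuration: one nested dataclass, YAML round-trip, hashing.

Defaults mirror the analysis conditions throughout the package: 2-mm
censoring, 5 noise principal components, 0.01-0.1 Hz band, F > 5 component
threshold, 25th/75th distance percentiles, 1000 bootstrap iterations on 50%
subsamples, stage boundaries at gestational weeks 26 and 29.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .cohort import NoiseConfig
from .preprocess import PreprocessConfig

__all__ = ["CohortConfig", "InferenceConfig", "GrowthConfig", "PipelineConfig"]


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 32
    n_regions: int = 70
    ga_min: float = 21.0
    ga_max: float = 37.0
    sampler: str = "uniform"  # or "stratified" (8/8/16 by stage)
    atlas_seed: int = 0


@dataclass(frozen=True)
class InferenceConfig:
    screen_n_sim: int = 1000
    screen_alpha: float = 0.05
    # The spatial-closeness screen is a parallel analysis by default; set
    # True to use it as a pre-filter restricting the NBS edge set.
    screen_first: bool = False
    threshold_f: float = 5.0
    n_perm: int = 5000
    alpha: float = 0.05


@dataclass(frozen=True)
class GrowthConfig:
    n_iter: int = 1000
    frac: float = 0.5
    expansion_fraction: float = 0.9
    robust: bool = True
    restrict_to_significant: bool = True
    stage_bounds_gw: tuple = (26.0, 29.0)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)

        def build(klass, key):
            sub = dict(d.pop(key, {}) or {})
            for name, value in sub.items():
                if isinstance(value, list):
                    sub[name] = tuple(value)
            return klass(**sub)

        return cls(
            cohort=build(CohortConfig, "cohort"),
            noise=build(NoiseConfig, "noise"),
            preprocess=build(PreprocessConfig, "preprocess"),
            inference=build(InferenceConfig, "inference"),
            growth=build(GrowthConfig, "growth"),
            **d,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
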
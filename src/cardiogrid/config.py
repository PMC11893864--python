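"""Run configuration: a keyed YAML document with per-stage seeds derived
from one global seed, round-tripping losslessly through its file form."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import ValidationError

_STAGE_OFFSETS = {"generator": 1, "split": 2, "order": 3, "backbone": 4,
                  "model": 5, "explain": 6, "qa": 7}


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    if stage not in _STAGE_OFFSETS:
        raise ValidationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class GeneratorSettings:
    backend: str = "copula"
    n: int = 1100
    seed: Optional[int] = None


@dataclass
class Tab2ImgSettings:
    distance: str = "signed"
    linkage: str = "average"
    target_side: int = 224


@dataclass
class BackboneSettings:
    backend: str = "toy"
    output_dim: int = 32
    seed: Optional[int] = None


@dataclass
class ModelSettings:
    family: str = "random_forest"
    grid: Optional[dict] = None
    folds: int = 5
    scoring: str = "accuracy"
    paper_mode: bool = False
    mode: str = "hybrid"


@dataclass
class ExplainSettings:
    background_size: int = 20
    n_permutations: int = 200
    method: str = "auto"
    seed: Optional[int] = None


@dataclass
class RunConfig:
    global_seed: int = 0
    schema_path: Optional[str] = None          # None -> bundled heart schema
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    tab2img: Tab2ImgSettings = field(default_factory=Tab2ImgSettings)
    backbone: BackboneSettings = field(default_factory=BackboneSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    explain: ExplainSettings = field(default_factory=ExplainSettings)

    def seed_for(self, stage: str) -> int:
        explicit = {"generator": self.generator.seed,
                    "backbone": self.backbone.seed,
                    "explain": self.explain.seed}.get(stage)
        if explicit is not None:
            return int(explicit)
        return derive_seed(self.global_seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            global_seed=int(d.get("global_seed", 0)),
            schema_path=d.get("schema_path"),
            generator=GeneratorSettings(**d.get("generator", {})),
            tab2img=Tab2ImgSettings(**d.get("tab2img", {})),
            backbone=BackboneSettings(**d.get("backbone", {})),
            model=ModelSettings(**d.get("model", {})),
            explain=ExplainSettings(**d.get("explain", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
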
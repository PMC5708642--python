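"""Pipeline configuration, serialisable to/from YAML or JSON."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .stains import StainVectors, default_he_vectors


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end pipeline.

    Defaults follow the method's tuned operating point: basin depth
    h = 30 grey levels, e = 3 cleaning erosions, diversity band
    [0.5, 0.9], two clusters.
    """

    h: int = 30
    e: int = 3
    d1: float = 0.5
    d2: float = 0.9
    k: int = 2
    watershed_mode: str = "intensity"
    consensus_method: str = "voting"   # "eac" | "voting" | "both"
    rng_seed: int = 0
    stain_vectors: list | None = None  # 3x3 floats; None -> standard H&E basis
    crop: bool = True
    n_kmeans: int = 10
    n_em: int = 10

    def __post_init__(self):
        if not 1 <= self.h <= 255:
            raise ParameterError(f"h must be in [1, 255], got {self.h}")
        if self.e < 0:
            raise ParameterError(f"e must be >= 0, got {self.e}")
        if not 0 <= self.d1 < self.d2 <= 1:
            raise ParameterError(f"need 0 <= D1 < D2 <= 1, got {self.d1}, {self.d2}")
        if self.consensus_method not in ("eac", "voting", "both"):
            raise ParameterError(f"unknown consensus method {self.consensus_method!r}")

    def vectors(self) -> StainVectors:
        if self.stain_vectors is None:
            return default_he_vectors()
        return StainVectors(np.asarray(self.stain_vectors, dtype=float))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path):
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d or {})
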
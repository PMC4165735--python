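"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import FormatError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the retrieval pipeline in one place.

    Defaults follow the method's stated operating point: 100x100 views,
    a 3000-word codebook; the rest are this implementation's documented
    choices (see docs/methods.md).
    """

    image_size: int = 100
    fill_factor: float = 0.9
    hessian_threshold: float = 1e-4
    octaves: int = 4
    intervals_per_octave: int = 4
    upright: bool = False
    codebook_k: int = 3000
    training_cap: int = 100_000
    seed: int = 0
    epsilon: float = 1.0
    combination: str = "sum"          # "sum" | "concat"
    distance: str = "symmetric"       # "symmetric" | "asymmetric"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"{path} does not hold a config mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
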
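"""Run configuration shared by the pipeline, the CLI and the reports."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for one prediction run; embedded in every report."""

    n: int
    alpha: Optional[List[float]] = None
    beta: Optional[List[float]] = None
    h: Optional[List[float]] = None
    seed: int = 0
    temperature: float = 1.0
    search_radius: int = 2
    g_max: int = 12
    mode: str = "intersect"          # intersect | summed
    backend: str = "native"          # native | normaliz
    sample_mode: str = "deterministic"  # deterministic | stochastic
    sample_count: int = 1

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"pathway length must be >= 3, got {self.n}")
        if self.mode not in ("intersect", "summed"):
            raise ValueError(f"mode must be intersect or summed, got {self.mode!r}")
        if self.backend not in ("native", "normaliz"):
            raise ValueError(f"backend must be native or normaliz, got {self.backend!r}")
        if self.sample_mode not in ("deterministic", "stochastic"):
            raise ValueError(f"sample_mode must be deterministic or stochastic")
        if self.temperature <= 0 or self.search_radius <= 0 or self.g_max < 0:
            raise ValueError("temperature/search_radius/g_max out of range")
        for name in ("alpha", "beta", "h"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n:
                raise ValueError(f"{name} must have length {self.n}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        return cls(**doc)
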
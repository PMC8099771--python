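"""Run configuration: filter thresholds plus pipeline-wide constants."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .calling import FilterConfig


@dataclass
class RunConfig:
    """Configuration carried through a pipeline run.

    The seed is recorded in the provenance block of every output table so
    runs are reproducible from their artifacts alone.
    """

    filters: FilterConfig = field(default_factory=FilterConfig)
    beta: float = 0.1089
    generation_time: float = 11.0
    cluster_window: int = 20_000
    mosaic_max_fraction: float = 0.05
    phase_window: int = 230
    seed: int = 0

    def __post_init__(self) -> None:
        import math

        for f in dataclasses.fields(self.filters):
            if not math.isfinite(float(getattr(self.filters, f.name))):
                raise ValueError(f"non-finite filter threshold {f.name}")

    def provenance(self) -> dict:
        block = {"seed": self.seed, "beta": self.beta}
        block.update(
            {f"filter.{f.name}": getattr(self.filters, f.name)
             for f in dataclasses.fields(self.filters)}
        )
        return block

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        filters = FilterConfig(**data.pop("filters", {}))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(filters=filters, **data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
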
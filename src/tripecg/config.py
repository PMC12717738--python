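"""Run configuration: every constant the method leaves open lives here.

A RunConfig bundles the detector constants, the fiducial threshold
configuration, the junction-exclusion width and the TAM aggregation rule,
and serializes to/from a plain JSON text file so that every analysis can be
reproduced from its config echo.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .beats import DetectorConfig
from .fiducials import ThresholdConfig
from .pipeline import PipelineConfig
from .triplicate import JUNCTION_EXCLUSION_MS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    junction_exclusion_ms: float = JUNCTION_EXCLUSION_MS
    tam_aggregate: str = "mean"  # 'mean' | 'median'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tam_aggregate not in ("mean", "median"):
            raise ValueError(f"tam_aggregate must be 'mean' or 'median', "
                             f"got {self.tam_aggregate!r}")
        if self.junction_exclusion_ms < 0:
            raise ValueError("junction_exclusion_ms must be >= 0")

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(detector=self.detector, thresholds=self.thresholds)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=2, default=list) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())

        def build(dc_cls, data):
            fields = {f.name: f for f in dataclasses.fields(dc_cls)}
            kwargs = {}
            for k, v in data.items():
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r} for {dc_cls.__name__}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return dc_cls(**kwargs)

        return cls(
            detector=build(DetectorConfig, raw.get("detector", {})),
            thresholds=build(ThresholdConfig, raw.get("thresholds", {})),
            junction_exclusion_ms=raw.get("junction_exclusion_ms", JUNCTION_EXCLUSION_MS),
            tam_aggregate=raw.get("tam_aggregate", "mean"),
            seed=raw.get("seed", 0),
        )
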
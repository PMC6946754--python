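"""Run configuration: one object tying instrument, drift, quantification,
peak-extraction and statistics settings together, serializable to YAML or
JSON and hashable so every output can record exactly which configuration
produced it."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .peaks import PeakConfig
from .quant import DriftConditions, QuantParams
from .simulate import ExperimentDesign, InstrumentParams

__all__ = ["StatsConfig", "RunConfig"]


@dataclass
class StatsConfig:
    """Statistics settings for the screening stage."""

    alpha: float = 0.05
    bonferroni_family: int | None = None  # None -> number of compounds tested
    n_boot: int = 1999
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with traceable defaults."""

    instrument: InstrumentParams = field(default_factory=InstrumentParams)
    drift: DriftConditions = field(default_factory=DriftConditions)
    quant: QuantParams = field(default_factory=QuantParams)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    stats: StatsConfig = field(default_factory=StatsConfig)
    #: reference ions for internal calibration (Hill strings)
    reference_ions: list[str] = field(
        default_factory=lambda: ["H3O18+", "C3H7O+", "C10H17+"])
    #: ions quantified into the emission table (Hill strings)
    target_ions: list[str] = field(default_factory=lambda: ["C5H9+"])

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub: dict):
            names = {f.name for f in dataclasses.fields(klass)}
            kwargs = {k: v for k, v in sub.items() if k in names}
            if klass is InstrumentParams and "mz_range" in kwargs:
                kwargs["mz_range"] = tuple(kwargs["mz_range"])
            if klass is QuantParams:
                for key in ("rate_overrides", "transmission"):
                    if key in kwargs:
                        kwargs[key] = {float(k): v for k, v in kwargs[key].items()}
            return klass(**kwargs)

        return cls(
            instrument=build(InstrumentParams, d.get("instrument", {})),
            drift=build(DriftConditions, d.get("drift", {})),
            quant=build(QuantParams, d.get("quant", {})),
            peaks=build(PeakConfig, d.get("peaks", {})),
            design=build(ExperimentDesign, d.get("design", {})),
            stats=build(StatsConfig, d.get("stats", {})),
            reference_ions=list(d.get("reference_ions",
                                      ["H3O18+", "C3H7O+", "C10H17+"])),
            target_ions=list(d.get("target_ions", ["C5H9+"])),
        )

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
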
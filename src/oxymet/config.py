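"""Run configuration: schema-validated parameters for every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config"]


class NirsConfig(BaseModel):
    water_fraction: float = Field(0.80, gt=0, le=1)
    smoothing_window: int = Field(11, ge=5)
    smoothing_polyorder: int = Field(3, ge=1)
    dhb_window_nm: tuple[float, float] = (720.0, 800.0)
    water_window_nm: tuple[float, float] = (800.0, 850.0)
    cco_window_nm: tuple[float, float] = (780.0, 900.0)
    plateau_top_fraction: float = Field(0.25, gt=0, le=1)
    plateau_smooth_seconds: float = Field(5.0, ge=0)

    @field_validator("smoothing_window")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        return v


class ProtocolConfig(BaseModel):
    sampling_rate_hz: float = Field(6.0, gt=0)
    total_duration_s: float = Field(1500.0, gt=0)
    anoxia_window_s: tuple[float, float] | None = (1440.0, 1490.0)
    averaging_window_s: tuple[float, float] = (0.0, 840.0)
    decimation: int = Field(10, ge=1)
    noise_sd_od: float = Field(1e-3, ge=0)


class AslConfig(BaseModel):
    lambda_partition: float = Field(0.90, gt=0)
    alpha_label: float = Field(0.70, gt=0, le=1)
    noise_sd: float = Field(20.0, ge=0)
    t1_cortex_s: float = Field(1.9, gt=0)
    m0: float = Field(1000.0, gt=0)


class OximetryConfig(BaseModel):
    arterial_fraction: float = Field(0.25, gt=0, lt=1)
    k_O2: float = Field(0.107, gt=0)
    sao2_source: str = "fixed"


class StatsConfig(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    posthoc: str = "ranksum"
    trajectory_method: str = "per_day"


class RunConfig(BaseModel):
    """Complete, schema-validated configuration of one pipeline run."""

    seed: int = 1
    groups: list[str] = ["naive", "cfa_ptx", "eae"]
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    nirs: NirsConfig = Field(default_factory=NirsConfig)
    asl: AslConfig = Field(default_factory=AslConfig)
    oximetry: OximetryConfig = Field(default_factory=OximetryConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    verbosity: str = "info"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_protocol(self):
        from .nirs import NirsProtocol

        return NirsProtocol(
            sampling_rate=self.protocol.sampling_rate_hz,
            total_duration=self.protocol.total_duration_s,
            anoxia_window=self.protocol.anoxia_window_s,
            averaging_window=self.protocol.averaging_window_s,
        )

    def to_oximetry_params(self):
        from .oximetry import OximetryParams

        src = "measured-trace" if self.oximetry.sao2_source == "measured-trace" else "fixed"
        return OximetryParams(self.oximetry.arterial_fraction, self.oximetry.k_O2, src)

    def to_asl_params(self):
        from .asl import AslModelParams

        return AslModelParams(self.asl.lambda_partition, self.asl.alpha_label)


def load_config(path=None) -> RunConfig:
    """Load YAML/JSON config; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)
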
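"""Structured run configuration (YAML) shared by the CLI subcommands.

One versioned schema validates every block before any computation runs;
unknown keys are rejected so typos fail loudly.  All randomness flows from
the single top-level ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .channel_mechanics import ChannelGeometry, FluidProperties
from .eec_pump import PumpConfig
from .transient_sim import ActuatorModel, StrainWaveform

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelBlock(_Strict):
    width_um: float = Field(gt=0)
    height_um: float = Field(gt=0)
    length_um: float = Field(gt=0)

    def build(self) -> ChannelGeometry:
        return ChannelGeometry(self.width_um, self.height_um, self.length_um)


class FluidBlock(_Strict):
    viscosity_mpas: float = Field(default=28.0, gt=0)
    poisson_ratio: float = Field(default=0.5, ge=0.0, le=0.5)

    def build(self) -> FluidProperties:
        return FluidProperties(self.viscosity_mpas, self.poisson_ratio)


class DeviceBlock(_Strict):
    left: ChannelBlock
    right: ChannelBlock
    left_observation: Optional[ChannelBlock] = None
    right_observation: Optional[ChannelBlock] = None
    stroke_volume_uL: float = Field(default=0.1, gt=0)

    def build(self, fluid: FluidProperties) -> PumpConfig:
        return PumpConfig(
            left=self.left.build(),
            right=self.right.build(),
            stroke_volume=self.stroke_volume_uL,
            fluid=fluid,
            left_observation=(
                self.left_observation.build() if self.left_observation else None
            ),
            right_observation=(
                self.right_observation.build() if self.right_observation else None
            ),
        )


class WaveformBlock(_Strict):
    amplitude: float = Field(ge=0)
    ramp_time_s: float = Field(default=1.0, ge=0)
    hold_time_s: float = Field(default=15.0, ge=0)
    release_time_s: float = Field(default=1.0, ge=0)
    wait_time_s: float = Field(default=15.0, ge=0)
    n_cycles: int = Field(default=1, ge=1)

    def build(self) -> StrainWaveform:
        return StrainWaveform(
            amplitude=self.amplitude,
            ramp_time=self.ramp_time_s,
            hold_time=self.hold_time_s,
            release_time=self.release_time_s,
            wait_time=self.wait_time_s,
            n_cycles=self.n_cycles,
        )


class ActuatorBlock(_Strict):
    rest_volume_uL: float = Field(default=1.0, gt=0)
    dilatation: float = Field(default=2.0, gt=0)
    compliance_uL_per_pa: float = Field(default=9.03e-3, gt=0)

    def build(self) -> ActuatorModel:
        return ActuatorModel(
            rest_volume=self.rest_volume_uL,
            dilatation=self.dilatation,
            compliance=self.compliance_uL_per_pa,
        )


class SweepBlock(_Strict):
    ar_lo: float = Field(default=0.1, gt=0)
    ar_hi: float = Field(default=10.0, gt=0)
    n_grid: int = Field(default=101, ge=2)
    strain: float = Field(default=0.1, ge=0)
    area_policy: Literal["equal", "right_scaled"] = "equal"
    area_factor: float = Field(default=1.5, gt=0)
    model: Literal["exact", "approximate"] = "approximate"


class FootprintBlock(_Strict):
    center_mm: tuple[float, float] = (0.0, 0.0)
    orientation_deg: float = 0.0
    radius_mm: Optional[float] = None
    vertices_mm: Optional[list[tuple[float, float]]] = None
    name: str = "sensor"


class PathsBlock(_Strict):
    output_dir: str = "samp-output"
    series_csv: Optional[str] = None
    strain_field_csv: Optional[str] = None


class RunConfig(_Strict):
    schema_version: int = 1
    seed: int = 0
    device: Optional[DeviceBlock] = None
    fluid: FluidBlock = FluidBlock()
    waveform: Optional[WaveformBlock] = None
    actuator: ActuatorBlock = ActuatorBlock()
    sweep: SweepBlock = SweepBlock()
    footprint: Optional[FootprintBlock] = None
    paths: PathsBlock = PathsBlock()

    @field_validator("schema_version")
    @classmethod
    def _known_version(cls, v: int) -> int:
        if v != 1:
            raise ValueError(f"unsupported schema_version {v}")
        return v

    def content_hash(self) -> str:
        """Stable hash of the validated config, for run manifests."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
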
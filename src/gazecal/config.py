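"""Schema-validated run configuration (YAML or JSON).

Unknown keys are rejected so typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import RigGeometry
from .simulate import NoiseModel, TrackerForwardModel

__all__ = [
    "GeometryConfig",
    "ForwardModelConfig",
    "NoiseConfig",
    "SimulatorConfig",
    "CalibrationConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    screen_origin_in_eye_frame: tuple[float, float, float] = (0.0, 30.0, -30.0)
    work_area_cm: tuple[float, float] = (20.0, 9.0)
    refresh_hz: float = Field(60.0, gt=0)
    screen_extent_cm: float = Field(30.0, gt=0)

    def build(self) -> RigGeometry:
        return RigGeometry(
            screen_origin_in_eye_frame=self.screen_origin_in_eye_frame,
            work_area_cm=self.work_area_cm,
            screen_refresh_hz=self.refresh_hz,
            screen_extent_cm=self.screen_extent_cm,
        )


class ForwardModelConfig(_Strict):
    camera_position: tuple[float, float, float] = (0.0, 55.0, -35.0)
    eyeball_radius_cm: float = Field(1.2, gt=0)
    span_volts: float = Field(3.0, gt=0)
    voltage_range: tuple[float, float] = (-5.0, 5.0)
    quantization_v: float = Field(2.0 ** -15, ge=0)

    def build(self, geometry: RigGeometry) -> TrackerForwardModel:
        return TrackerForwardModel.for_rig(
            geometry,
            span_volts=self.span_volts,
            camera_position=self.camera_position,
            eyeball_radius=self.eyeball_radius_cm,
            voltage_range=self.voltage_range,
            quantization_v=self.quantization_v,
        )


class NoiseConfig(_Strict):
    sample_noise_deg_rms: float = Field(0.0, ge=0)
    voltage_noise_v: float = Field(0.0, ge=0)
    trial_scatter_deg_sd: float = Field(0.0, ge=0)
    head_shift_v: tuple[float, float] = (0.0, 0.0)
    blink_prob: float = Field(0.0, ge=0, le=1)

    def build(self, seed: Optional[int] = None) -> NoiseModel:
        return NoiseModel(
            sample_noise_deg_rms=self.sample_noise_deg_rms,
            voltage_noise_v=self.voltage_noise_v,
            trial_scatter_deg_sd=self.trial_scatter_deg_sd,
            head_shift_v=self.head_shift_v,
            blink_prob=self.blink_prob,
            seed=seed,
        )


class SimulatorConfig(_Strict):
    forward_model: ForwardModelConfig = ForwardModelConfig()
    noise: NoiseConfig = NoiseConfig()
    seed: int = 0
    n_rows: int = Field(5, ge=2)
    n_cols: int = Field(5, ge=2)
    n_repeats: int = Field(3, ge=1)
    window_ms: float = Field(100.0, gt=0)
    rate_hz: float = Field(1000.0, gt=0)


class CalibrationConfig(_Strict):
    order: Literal[2, 3, 4] = 4
    fit_on: Literal["mesh", "anchors"] = "mesh"
    regrid_resolution: int = Field(50, ge=2)
    rejection_sd_multiple: float = Field(5.0, gt=0)


class RunConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    simulator: SimulatorConfig = SimulatorConfig()
    calibration: CalibrationConfig = CalibrationConfig()


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file (unknown keys rejected)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig.model_validate(data)
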
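"""Run configuration: schema-validated key/value tree (YAML).

Every dynamics default equals the published model parameters; the shipped
``data/default_config.yaml`` spells them all out literally.  Unknown keys are
rejected so silent typos cannot change an experiment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cardiac_model import (DynamicParams, PhantomConfig, RegionLabel,
                            StimulusProtocol)
from .signal_processing import FilterChainSpec

__all__ = ["RunConfig", "load_config", "default_config", "config_hash"]

_REGION_KEYS = {r.value: r for r in RegionLabel}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomModel(_Strict):
    grid_shape: tuple[int, int] = (150, 150)
    spacing: float = 0.75
    include_electrode_layer: bool = True
    geometry: dict[str, object] = Field(default_factory=dict)

    @field_validator("geometry")
    @classmethod
    def _known_geometry_keys(cls, v: dict) -> dict:
        allowed = {f.name for f in dataclasses.fields(PhantomConfig)} - {
            "grid_shape", "spacing", "include_electrode_layer", "params"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        return v


class DynamicsModel(_Strict):
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 1.0
    delta: float = 0.0
    theta: float = 0.15
    cubic_gain: float = 2.1
    epsilon: dict[str, float] = Field(default_factory=dict)
    diffusion: dict[str, float] = Field(default_factory=dict)
    theta_overrides: dict[str, float] = Field(default_factory=dict)

    @field_validator("epsilon", "diffusion", "theta_overrides")
    @classmethod
    def _known_regions(cls, v: dict) -> dict:
        unknown = set(v) - set(_REGION_KEYS)
        if unknown:
            raise ValueError(f"unknown region names: {sorted(unknown)}")
        return v

    def to_params(self) -> DynamicParams:
        base = DynamicParams(alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                             delta=self.delta, theta=self.theta,
                             cubic_gain=self.cubic_gain)
        eps = dict(base.epsilon_by_region)
        eps.update({_REGION_KEYS[k]: v for k, v in self.epsilon.items()})
        diff = dict(base.diffusion_by_region)
        diff.update({_REGION_KEYS[k]: v for k, v in self.diffusion.items()})
        theta = dict(base.theta_by_region)
        theta.update({_REGION_KEYS[k]: v for k, v in self.theta_overrides.items()})
        return dataclasses.replace(base, epsilon_by_region=eps,
                                   diffusion_by_region=diff, theta_by_region=theta)


class ProtocolModel(_Strict):
    period: float = 1200.0
    amplitude: float = 0.5
    pulse_width: float = 12.0
    start: float = 20.0
    cycle_seconds: float = 0.8

    def to_protocol(self) -> StimulusProtocol:
        return StimulusProtocol(period=self.period, amplitude=self.amplitude,
                                pulse_width=self.pulse_width, start=self.start)


class SimulateModel(_Strict):
    duration_beats: float = 8.0


class SynthModel(_Strict):
    mode: Literal["static", "dynamic"] = "static"
    fs: float = 500.0
    mean_bpm: float = 70.0
    sdnn_s: float = 0.03
    duration_s: float = 300.0
    experimental_preset: str = "sitting"
    control_preset: str = "sitting"
    dynamic_schedule: tuple[str, ...] = ("sitting", "office", "turning", "stepping")
    segment_s: float = 120.0


class FilterModel(_Strict):
    highpass_cutoff_hz: float = 0.5
    lowpass_cutoff_hz: float = 100.0
    notch_freqs_hz: tuple[float, ...] = (50.0, 100.0)
    highpass_order: int = 4
    lowpass_order: int = 4
    notch_q: float = 30.0

    def to_spec(self) -> FilterChainSpec:
        return FilterChainSpec(
            highpass_cutoff_hz=self.highpass_cutoff_hz,
            lowpass_cutoff_hz=self.lowpass_cutoff_hz,
            notch_freqs_hz=tuple(self.notch_freqs_hz),
            highpass_order=self.highpass_order,
            lowpass_order=self.lowpass_order,
            notch_q=self.notch_q)


class FiltersModel(_Strict):
    static_arm: FilterModel = Field(default_factory=lambda: FilterModel(highpass_cutoff_hz=0.5))
    modified_arm: FilterModel = Field(default_factory=lambda: FilterModel(highpass_cutoff_hz=0.25))


class RunConfig(_Strict):
    seed: int = 1
    output_dir: str = "results"
    phantom: PhantomModel = Field(default_factory=PhantomModel)
    dynamics: DynamicsModel = Field(default_factory=DynamicsModel)
    protocol: ProtocolModel = Field(default_factory=ProtocolModel)
    simulate: SimulateModel = Field(default_factory=SimulateModel)
    synth: SynthModel = Field(default_factory=SynthModel)
    filters: FiltersModel = Field(default_factory=FiltersModel)

    def phantom_config(self) -> PhantomConfig:
        geometry = {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                        if isinstance(v, list) else v)
                    for k, v in self.phantom.geometry.items()}
        return PhantomConfig(grid_shape=tuple(self.phantom.grid_shape),
                             spacing=self.phantom.spacing,
                             include_electrode_layer=self.phantom.include_electrode_layer,
                             params=self.dynamics.to_params(),
                             **geometry)  # type: ignore[arg-type]


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def default_config() -> RunConfig:
    text = resources.files("unipos_ecg").joinpath("data/default_config.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
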
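"""Run configuration: typed, defaulted, range-checked, round-trippable.

Configs are YAML documents; unknown keys are rejected. An empty document
yields the all-defaults configuration with a freshly generated seed (recorded
in the run manifest so the run stays reproducible).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError

STAGES = ("simulate", "quantify", "features", "classify", "ephys")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EffectSection(_Model):
    length_delta_um: float = 0.0
    ais_scale: float = Field(1.0, gt=0)
    dendrite_scale: float = Field(1.0, gt=0)


class CohortSection(_Model):
    n_per_condition: int = Field(40, ge=2)
    ais_length_um: float = Field(30.0, gt=0)
    ais_peak_amp: float = Field(1000.0, gt=0)
    dendrite_level: float = Field(150.0, gt=0)
    background_level: float = Field(100.0, ge=0)
    noise_sd: float = Field(30.0, ge=0)
    pixel_size_um: float = Field(0.28, gt=0)
    profile_span_um: float = Field(40.0, ge=25)
    dendrite_span_um: float = Field(15.0, gt=0)
    amp_cv: float = Field(0.2, ge=0)
    length_sd_um: float = Field(2.5, ge=0)
    ais_start_um: float = Field(2.0, ge=0)


class ProtocolSection(_Model):
    step_start_pa: float = 10.0
    step_increment_pa: float = 10.0
    step_duration_ms: float = Field(500.0, gt=0)
    n_steps: int = Field(10, ge=1)
    onset_ms: float = Field(100.0, ge=0)
    tail_ms: float = Field(100.0, ge=0)


class CellSection(_Model):
    rin_mohm: float = Field(600.0, gt=0)
    tau_ms: float = Field(50.0, gt=0)
    rest_mv: float = -60.0
    spike_threshold_mv: float = -40.0
    sample_interval_ms: float = Field(0.05, gt=0)
    noise_sd_mv: float = Field(0.2, ge=0)
    spike_amp_mv: float = Field(100.0, gt=0)
    spike_rise_ms: float = Field(1.0, gt=0)
    spike_fall_ms: float = Field(1.0, gt=0)


class EphysSection(_Model):
    n_cells: int = Field(4, ge=1)
    cell: CellSection = Field(default_factory=CellSection)
    firing_protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    passive_protocol: ProtocolSection = Field(default_factory=lambda: ProtocolSection(
        step_start_pa=-120.0, step_increment_pa=20.0, step_duration_ms=200.0, n_steps=8))
    rin_cv: float = Field(0.2, ge=0)


class QuantifySection(_Model):
    threshold_fraction: float = Field(0.15, gt=0, lt=1)
    smooth_window: int = Field(3, ge=1)
    length_unit: Literal["um", "px"] = "um"
    control_label: str = "control"

    @field_validator("smooth_window")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("smooth_window must be odd")
        return v


class ClassifySection(_Model):
    kernel: Literal["rbf", "linear", "poly", "sigmoid"] = "rbf"
    c: float = Field(1.0, gt=0)
    n_repeats: int = Field(100, ge=1)
    train_fraction: float = Field(0.7, gt=0, lt=1)
    stratified: bool = False
    use_normalized_adr: bool = False


class RunConfig(_Model):
    """Top-level pipeline configuration."""

    stages: List[Literal["simulate", "quantify", "features", "classify", "ephys"]] = \
        Field(default_factory=lambda: list(STAGES))
    out_dir: str = "runs/run"
    seed: Optional[int] = None
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"
    cohort_csv: Optional[str] = None        # external input when not simulating
    ground_truth_json: Optional[str] = None
    cohort: CohortSection = Field(default_factory=CohortSection)
    effect: EffectSection = Field(default_factory=EffectSection)
    quantify: QuantifySection = Field(default_factory=QuantifySection)
    classify: ClassifySection = Field(default_factory=ClassifySection)
    ephys: EphysSection = Field(default_factory=EphysSection)

    def resolved_seed(self) -> int:
        if self.seed is None:
            # generated once and recorded in the manifest
            object.__setattr__(self, "seed", int(np.random.SeedSequence().entropy % (2 ** 31)))
        return int(self.seed)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and log level excluded)."""
        payload = self.model_dump()
        for presentation_key in ("out_dir", "log_level", "stages"):
            payload.pop(presentation_key, None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def validate_config(text: str) -> RunConfig:
    """Parse and validate a YAML config document; '' means all defaults."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def load_config(path: Optional[Path]) -> RunConfig:
    if path is None:
        return validate_config("")
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    return validate_config(path.read_text())
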
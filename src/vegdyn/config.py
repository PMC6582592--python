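"""Project configuration: YAML loading with strict validation.

Unknown keys are rejected, type errors are aggregated, and file references
are checked before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["ProjectConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(Exception):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    output_dir: str = "outputs"
    state_table: str | None = None
    initial_state_raster: str | None = None
    residence_raster: str | None = None
    soil_depth_raster: str | None = None
    soil_fertility_raster: str | None = None
    region_raster: str | None = None
    climate: str | None = None
    model_dir: str | None = None
    examples: str | None = None


class KernelConfigSection(_Strict):
    preset: str = "eight_state"  # three_state | eight_state | neighbourhood | gradient
    seed: int = 0


class SynthConfigSection(_Strict):
    rows: int = Field(40, ge=1)
    cols: int = Field(40, ge=1)
    years: int = Field(120, ge=1)
    n_regions: int = Field(1, ge=1)
    mean_temperature: float = 9.0
    temperature_range: float = 0.0  # linear north-south spread across regions


class ModelConfigSection(_Strict):
    hidden: list[int] = [128, 128]
    activation: str = "relu"
    dropout: float = Field(0.1, ge=0.0, lt=1.0)
    learning_rate: float = Field(1e-3, gt=0)
    batch_size: int = Field(256, ge=1)
    epochs: int = Field(10, ge=1)
    climate_encoding: str = "monthly"
    shared_trunk: bool = True


class RunConfigSection(_Strict):
    years: int = Field(100, ge=0)
    seed: int = 0
    output_every: int = Field(0, ge=0)
    initial_residence: int = Field(0, ge=0)


class ProjectConfig(_Strict):
    schema_version: int = 1
    paths: PathsConfig = PathsConfig()
    kernel: KernelConfigSection = KernelConfigSection()
    synth: SynthConfigSection = SynthConfigSection()
    model: ModelConfigSection = ModelConfigSection()
    run: RunConfigSection = RunConfigSection()


#: path fields that must already exist on disk when set
_INPUT_PATHS = (
    "state_table",
    "initial_state_raster",
    "residence_raster",
    "soil_depth_raster",
    "soil_fertility_raster",
    "region_raster",
    "climate",
    "examples",
)


def load_config(path, check_files: bool = True) -> ProjectConfig:
    """Load and fully validate a YAML project configuration.

    Raises :class:`ConfigError` listing every problem found (unknown keys,
    type mismatches, missing referenced files) rather than stopping at the
    first one.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text()) or {}
    problems: list[str] = []
    try:
        cfg = ProjectConfig.model_validate(raw)
    except ValidationError as e:
        for err in e.errors():
            loc = ".".join(str(p) for p in err["loc"])
            problems.append(f"{loc}: {err['msg']}")
        raise ConfigError(problems) from None
    if check_files:
        base = path.parent
        for name in _INPUT_PATHS:
            value = getattr(cfg.paths, name)
            if value is not None and not (base / value).exists():
                problems.append(f"paths.{name}: file not found: {base / value}")
    if problems:
        raise ConfigError(problems)
    return cfg


def save_config(cfg: ProjectConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def config_hash(cfg: ProjectConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
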
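"""Configuration parsing, result serialization and run metadata.

Configs are YAML (JSON is valid YAML) parsed into a strict pydantic model:
unknown keys are rejected with a path-qualified message, and any command
with a stochastic component requires an explicit seed.  Every artifact the
pipeline writes embeds the package version, a hash of the resolved config,
and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fluxes import ExposureSchedule
from .species import SUPPORTED_SPECIES, SpeciesParameterSet, load_species_defaults
from .synth import canned_schedules

log = logging.getLogger("mnpbpk")

try:
    __version__ = metadata.version("mnpbpk")
except metadata.PackageNotFoundError:   # pragma: no cover - source tree use
    __version__ = "0.0.dev"


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    air_conc: float = Field(0.0, ge=0)
    hours_per_day: float = Field(0.0, ge=0, le=24)
    days_per_week: int = Field(7, ge=1, le=7)
    duration_days: float = Field(0.0, ge=0)
    diet_rate: Optional[float] = Field(None, ge=0)
    diet_ppm: Optional[float] = Field(None, ge=0)
    food_intake: Optional[float] = Field(None, ge=0)
    start_time: float = 0.0

    def build(self) -> ExposureSchedule:
        return ExposureSchedule(**self.model_dump())


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rtol: float = Field(1e-8, gt=0)
    atol: float = Field(1e-10, gt=0)


class MonteCarloConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = Field(10_000, ge=1)
    air_levels: list[float] = [0.00005, 0.0005, 0.005, 0.05, 0.2, 0.5]
    duration_days: float = Field(365.0, gt=0)


class RunConfig(BaseModel):
    """Top-level run description (strict: unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    species: str
    schedule: Union[str, ScheduleConfig, None] = None
    scenario: Optional[str] = None
    overrides: dict[str, float] = {}
    seed: Optional[int] = None
    out_dir: str = "results"
    solver: SolverConfig = SolverConfig()
    monte_carlo: Optional[MonteCarloConfig] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.species not in SUPPORTED_SPECIES:
            raise ValueError(
                f"species: unknown species {self.species!r}; "
                f"supported: {list(SUPPORTED_SPECIES)}")
        if isinstance(self.schedule, str) and self.schedule not in canned_schedules():
            raise ValueError(
                f"schedule: unknown named schedule {self.schedule!r}; "
                f"available: {sorted(canned_schedules())}")
        if self.monte_carlo is not None and self.seed is None:
            raise ValueError("seed: a seed is mandatory for stochastic runs")
        return self


def parse_config(source) -> RunConfig:
    """Parse a YAML/JSON config from a path or literal text."""
    text = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        if "\n" not in str(source) and p.suffix in (".yaml", ".yml", ".json") and p.exists():
            text = p.read_text()
        elif isinstance(source, Path):
            raise FileNotFoundError(source)
        else:
            text = str(source)
    elif hasattr(source, "read"):
        text = source.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return RunConfig(**data)


def emit_config(cfg: RunConfig) -> str:
    """Serialize a resolved config; re-parsing gives an identical config."""
    return yaml.safe_dump(cfg.model_dump(exclude_none=True), sort_keys=True)


def resolve_params(cfg: RunConfig) -> SpeciesParameterSet:
    params = load_species_defaults(cfg.species)
    for path, value in cfg.overrides.items():
        params.get(path)  # validate
        params.set(path, value)
        params.provenance[path] = "config override"
    return params


def resolve_schedule(cfg: RunConfig, params: SpeciesParameterSet) -> ExposureSchedule:
    import dataclasses

    if cfg.schedule is None:
        sched = ExposureSchedule()
    elif isinstance(cfg.schedule, str):
        sched = canned_schedules()[cfg.schedule]
    else:
        sched = cfg.schedule.build()
    if sched.diet_rate is None and sched.diet_ppm is None:
        sched = dataclasses.replace(sched, **params.default_diet)
    return sched


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(emit_config(cfg).encode()).hexdigest()[:12]


def artifact_header(cfg: Optional[RunConfig], seed: Optional[int]) -> str:
    h = config_hash(cfg) if cfg is not None else "none"
    return f"# mnpbpk {__version__} config_hash={h} seed={seed}\n"


def write_table(df: pd.DataFrame, path, cfg: Optional[RunConfig] = None,
                seed: Optional[int] = None) -> None:
    """CSV with a provenance comment header and stable float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(artifact_header(cfg, seed))
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    log.info("wrote %s (%d rows)", path, len(df))


def write_json(obj: dict, path, cfg: Optional[RunConfig] = None,
               seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"mnpbpk_version": __version__, "seed": seed,
            "config_hash": config_hash(cfg) if cfg is not None else None}
    with open(path, "w") as fh:
        json.dump({"meta": meta, **obj}, fh, indent=2, sort_keys=True)
    log.info("wrote %s", path)
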